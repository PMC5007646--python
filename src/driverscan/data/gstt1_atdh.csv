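# GSTT1 null/present genotype counts: ATDH cases vs non-ATDH controls.
# Known inconsistency in the published source table: the Tang 2012 and
# Wang 2010 rows are identical and the column totals disagree with the
# narrative case/control counts; transcribed verbatim nonetheless.
study_id,ethnicity,case_null,case_present,control_null,control_present
Chatterjee 2009,Indian,3,48,3,97
Gupta 2013,Indian,11,39,30,216
Huang 2007,Chinese,24,39,25,38
Kim 2010,Korea,34,23,103,87
Leiro 2008,Spanish,17,18,16,44
Liu 2014,Chinese,13,7,97,46
Monteiro 2012,Brazilian,11,48,28,90
Rana 2014,Indian,14,41,79,164
Roy 2001,Indian,5,28,1,32
Singla 2013,Indian,8,9,102,289
Sotsuka 2011,Japanese,7,13,40,52
Tang 2012,Chinese,40,49,164,192
Teixeira 2011,Brazilian,4,22,27,114
Wang 2010,Chinese,40,49,164,192
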