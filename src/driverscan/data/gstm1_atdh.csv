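# GSTM1 null/present genotype counts: anti-tuberculosis drug-induced
# hepatotoxicity cases vs non-ATDH tuberculosis-patient controls.
study_id,ethnicity,case_null,case_present,control_null,control_present
Chatterjee 2009,Indian,25,26,49,51
Gupta 2013,Indian,21,29,61,185
Huang 2007,Chinese,42,21,29,34
Kim 2010,Korea,26,31,104,86
Leiro 2008,Spanish,12,23,25,35
Liu 2014,Chinese,14,6,96,47
Monteiro 2012,Brazilian,21,38,34,84
Rana 2014,Indian,19,36,42,203
Roy 2001,Indian,17,16,8,25
Singla 2013,Indian,10,7,165,226
Sotsuka 2011,Japanese,12,8,50,42
Tang 2012,Chinese,55,34,203,153
Teixeira 2011,Brazilian,11,15,61,80
Wang 2010,Chinese,63,41,54,57
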