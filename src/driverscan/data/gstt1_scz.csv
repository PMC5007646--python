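# GSTT1 null/present genotype counts: schizophrenia cases vs healthy controls.
study_id,ethnicity,case_null,case_present,control_null,control_present
Gravina 2011,Italian,25,113,30,103
Matsuzawa 2008,Japanese,88,126,80,140
Raffa 2013,Tunisian,59,79,67,56
Saadat 2007,Iranian,52,240,99,193
Saruwatari 2013,Japanese,68,86,99,104
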