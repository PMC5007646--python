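# GSTM1 null/present genotype counts: schizophrenia cases vs healthy controls.
study_id,ethnicity,case_null,case_present,control_null,control_present
Gravina 2011,Italian,82,56,70,63
Harada 2001,Japanese,57,30,87,89
Matsuzawa 2008,Japanese,129,85,119,101
Pae 2004,Korean,70,41,61,69
Raffa 2013,Tunisian,79,59,63,60
Saruwatari 2013,Japanese,77,77,99,104
Watanabe 2010,Japanese,339,288,322,298
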