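tag,description,pod
"(0027,""GEMS_IMAG_01"",33)",ImagingOptions,kept
"(3f01,""INTELERAD MEDICAL SYSTEMS"",03)",SourceAE,deleted
"(7005,""TOSHIBA_MEC_CT3"",1c)",Contrast/Bolus Agent for Series Record,emptied
"(0009,""GEMS_PETD_01"",37)",Batch Description,deleted
"(0045,""GEMS_SENO_02"",26)",MAOBuffer,deleted
"(0009,""FDMS 1.0"",92)",KanjiDepartmentName,deleted
"(0009,""GEMS_IDEN_01"",30)",ServiceId,emptied
"(0043,""GEMS_PARM_01"",80)",Coil ID Data,kept
"(0021,""SIEMENS MR SDS 01"",19)",MR Phoenix Protocol,emptied
"(0023,""GEMS_STDY_01"",70)",StartTimeSecsInFirstAxial,offset
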