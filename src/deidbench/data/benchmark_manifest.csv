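modality,patients,studies,series,images,body_parts,manufacturers,shared_patients
CT,5,5,5,268,BLADDER:4|CHEST:1,GE MEDICAL SYSTEMS:2|PHILIPS:1|SIEMENS:1|TOSHIBA:1,
MR,3,3,5,150,KIDNEY:2|PELVIS:1,GE MEDICAL SYSTEMS:1|SIEMENS:2,
PT,5,5,6,1203,[BLANK]:1|BREAST:2|EXTREMITY:2,GE MEDICAL SYSTEMS:4|SIEMENS:1,
DX,4,4,4,10,CHEST:4,GE MEDICAL SYSTEMS:1|PHILIPS:3,
CR,3,3,4,4,CHEST:2|UTERUS:1,FUJIFILM:3,DX:1
MG,2,2,2,58,BREAST:2,LORAD:1|VICTRE:1,
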