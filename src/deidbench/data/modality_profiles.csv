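tag,name,type,modality,rule
"(0008,0016)",SOP Class UID,1,All,sop_class
"(0008,0018)",SOP Instance UID,1,All,uid_instance
"(0020,000d)",Study Instance UID,1,All,uid_study
"(0020,000e)",Series Instance UID,1,All,uid_series
"(0008,0060)",Modality,1,All,modality
"(0008,0020)",Study Date,2,All,study_date
"(0008,0030)",Study Time,2,All,fixed:120000
"(0008,0050)",Accession Number,2,All,empty
"(0008,0070)",Manufacturer,2,All,manufacturer
"(0008,0090)",Referring Physician's Name,2,All,empty
"(0010,0010)",Patient's Name,2,All,patient_name
"(0010,0020)",Patient ID,2,All,patient_id
"(0010,0030)",Patient's Birth Date,2,All,empty
"(0010,0040)",Patient's Sex,2,All,fixed:O
"(0018,0015)",Body Part Examined,3,All,body_part
"(0020,0010)",Study ID,2,All,study_id
"(0020,0011)",Series Number,2,All,series_number
"(0020,0013)",Instance Number,2,All,instance_number
"(0020,0060)",Laterality,2C,All,none
"(0028,0002)",Samples per Pixel,1,All,fixed:1
"(0028,0004)",Photometric Interpretation,1,All,fixed:MONOCHROME2
"(0028,0010)",Rows,1,All,rows
"(0028,0011)",Columns,1,All,cols
"(0028,0100)",Bits Allocated,1,All,fixed:16
"(0028,0101)",Bits Stored,1,All,fixed:16
"(0028,0102)",High Bit,1,All,fixed:15
"(0028,0103)",Pixel Representation,1,All,fixed:0
"(7fe0,0010)",Pixel Data,1,All,pixels
"(0008,1010)",Station Name,3,All,fixed:STATION01
"(0008,1030)",Study Description,3,All,desc_by_modality
"(0008,2111)",Derivation Description,3,All,fixed:DERIVED SECONDARY REVIEW
"(0012,0062)",Patient Identity Removed,3,All,fixed:YES
"(0012,0063)",De-identification Method,3,All,fixed:SYNTHETIC BASELINE
"(0028,0004)",Photometric Interpretation,1,CR,fixed:MONOCHROME2
"(0008,0008)",Image Type,1,CT,fixed:ORIGINAL\PRIMARY\AXIAL
"(0018,0060)",KVP,2,CT,fixed:120
"(0008,0068)",Presentation Intent Type,1,DX,fixed:FOR PRESENTATION
"(0008,0070)",Manufacturer,2,DX,manufacturer
"(0028,0120)",Pixel Padding Value,1C,DX,none
"(0018,1508)",Positioner Type,1,MG,fixed:MAMMOGRAPHIC
"(0040,0318)",Organ Exposed,1,MG,fixed:BREAST
"(0028,0100)",Bits Allocated,1,MR,fixed:16
"(0028,0101)",Bits Stored,1,MR,fixed:16
"(0020,0032)",Image Position (Patient),1,PT,fixed:0\0\0
"(0020,0037)",Image Orientation (Patient),1,PT,fixed:1\0\0\0\1\0
"(0008,0064)",Conversion Type,1,SC,fixed:WSD
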