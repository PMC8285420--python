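[
  {"tag": "(0010,0010)", "name": "Patient's Name", "scope": "Patient", "phi": ["patient_name"]},
  {"tag": "(0010,0020)", "name": "Patient ID", "scope": "Patient", "phi": ["patient_id"]},
  {"tag": "(0010,0030)", "name": "Patient's Birth Date", "scope": "Patient", "phi": ["birth_date"]},
  {"tag": "(0010,1040)", "name": "Patient's Address", "scope": "Patient", "phi": ["address"]},
  {"tag": "(0010,0021)", "name": "Issuer of Patient ID", "scope": "Patient", "phi": ["issuer"]},
  {"tag": "(0010,4000)", "name": "Patient Comments", "scope": "Patient", "phi": ["phone"],
   "retained": ["FOLLOW UP IN 6 MONTHS"], "assembly": "retained_first"},
  {"tag": "(0010,21b0)", "name": "Additional Patient History", "scope": "Patient",
   "phi": ["prior_facility"], "retained": ["PRIOR IMAGING REVIEWED AT"], "assembly": "retained_first"},

  {"tag": "(0008,0050)", "name": "Accession Number", "scope": "Study", "phi": ["accession:J"]},
  {"tag": "(0008,0080)", "name": "Institution Name", "scope": "Study", "phi": ["institution"]},
  {"tag": "(0008,0090)", "name": "Referring Physician's Name", "scope": "Study", "phi": ["referring_physician"]},
  {"tag": "(0008,1050)", "name": "Performing Physician's Name", "scope": "Study", "phi": ["performing_physician"]},
  {"tag": "(0008,1030)", "name": "Study Description", "scope": "Study",
   "phi": ["display_name"], "retained": ["$DESC"]},
  {"tag": "(0032,1000)", "name": "Scheduled Study Start Date", "scope": "Study",
   "phi": ["scheduled_date:J"], "vr": "DA"},
  {"tag": "(0032,1030)", "name": "Reason for Study", "scope": "Study", "retained": ["ROUTINE SCREENING"]},
  {"tag": "(0032,1060)", "name": "Requested Procedure Description", "scope": "Study", "retained": ["$DESC"]},
  {"tag": "(0032,1070)", "name": "Requested Contrast Agent", "scope": "Study",
   "modalities": ["CT", "MR"], "retained": ["IOHEXOL"]},
  {"tag": "(0032,4000)", "name": "Study Comments", "scope": "Study", "phi": ["comments_seed"],
   "retained": ["STABLE COMPARED TO PRIOR"], "assembly": "retained_first"},
  {"tag": "(0008,1080)", "name": "Admitting Diagnoses Description", "scope": "Study", "retained": ["HYPERTENSION"]},
  {"tag": "(3006,0006)", "name": "Structure Set Description", "scope": "Study",
   "modalities": ["CT"], "phi": ["struct_desc"]},
  {"tag": "(3006,0008)", "name": "Structure Set Date", "scope": "Study",
   "modalities": ["CT"], "phi": ["struct_date:J"], "vr": "DA"},

  {"tag": "(0008,1010)", "name": "Station Name", "scope": "Series", "op": "substitute", "phi": ["workstation"]},
  {"tag": "(0008,2111)", "name": "Derivation Description", "scope": "Series",
   "op": "string_replace", "old": "REVIEW", "phi": ["operator_display"]},
  {"tag": "(0018,1000)", "name": "Device Serial Number", "scope": "Series", "phi": ["device_serial"]},
  {"tag": "(0008,0041)", "name": "Data Set Subtype", "scope": "Series", "retained": ["SECONDARY"]},
  {"tag": "(0018,1250)", "name": "Receive Coil Name", "scope": "Series",
   "modalities": ["MR"], "retained": ["BODY"]},
  {"tag": "(0018,7006)", "name": "Detector Description", "scope": "Series",
   "modalities": ["DX", "CR", "MG"], "phi": ["detector_id"], "retained": ["FLAT PANEL DETECTOR"],
   "assembly": "retained_first"},
  {"tag": "(0018,0010)", "name": "Contrast/Bolus Agent", "scope": "Series",
   "modalities": ["CT", "MR"], "retained": ["IOHEXOL 350"]},
  {"tag": "(0018,1401)", "name": "Acquisition Device Processing Code", "scope": "Series",
   "modalities": ["CR", "DX"], "phi": ["proc_code"]},

  {"tag": "(0027,\"GEMS_IMAG_01\",33)", "name": "ImagingOptions", "scope": "Series",
   "manufacturers": ["GE MEDICAL SYSTEMS"], "modalities": ["CT"], "phi": ["imaging_options"]},
  {"tag": "(0009,\"GEMS_PETD_01\",37)", "name": "Batch Description", "scope": "Series",
   "manufacturers": ["GE MEDICAL SYSTEMS"], "modalities": ["PT"], "phi": ["batch_desc"]},
  {"tag": "(0009,\"GEMS_IDEN_01\",30)", "name": "ServiceId", "scope": "Series",
   "manufacturers": ["GE MEDICAL SYSTEMS"], "modalities": ["MR", "DX", "CR", "MG"], "phi": ["service_id"]},
  {"tag": "(0043,\"GEMS_PARM_01\",80)", "name": "Coil ID Data", "scope": "Series",
   "manufacturers": ["GE MEDICAL SYSTEMS"], "modalities": ["MR"], "phi": ["coil_id"]},
  {"tag": "(0023,\"GEMS_STDY_01\",70)", "name": "StartTimeSecsInFirstAxial", "scope": "Series",
   "manufacturers": ["GE MEDICAL SYSTEMS"], "modalities": ["CT", "PT"], "phi": ["start_secs"]},
  {"tag": "(0021,\"SIEMENS MR SDS 01\",19)", "name": "MR Phoenix Protocol", "scope": "Series",
   "manufacturers": ["SIEMENS"], "phi": ["phoenix"]},
  {"tag": "(0009,\"FDMS 1.0\",92)", "name": "KanjiDepartmentName", "scope": "Series",
   "manufacturers": ["FUJIFILM"], "phi": ["kanji_dept"]},
  {"tag": "(7005,\"TOSHIBA_MEC_CT3\",1c)", "name": "Contrast/Bolus Agent for Series Record", "scope": "Series",
   "manufacturers": ["TOSHIBA"], "retained": ["IOPAMIDOL 370"]},
  {"tag": "(3f01,\"INTELERAD MEDICAL SYSTEMS\",03)", "name": "SourceAE", "scope": "Series",
   "manufacturers": ["PHILIPS", "LORAD", "VICTRE"], "phi": ["source_ae"]},
  {"tag": "(0045,\"GEMS_SENO_02\",26)", "name": "MAOBuffer", "scope": "Series",
   "manufacturers": ["LORAD"], "phi": ["mao_buffer"]}
]
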