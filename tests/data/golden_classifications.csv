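patient_id,base,model1,model2,model3,step1_base,step1_plus_lasr
FIX000,normal,normal,normal,normal,normal,normal
FIX001,normal,normal,normal,normal,normal,normal
FIX002,normal,normal,normal,normal,normal,normal
FIX003,normal,normal,normal,normal,dysfunction,dysfunction
FIX004,normal,normal,normal,normal,dysfunction,dysfunction
FIX005,normal,normal,normal,normal,dysfunction,dysfunction
FIX006,elevated,elevated,elevated,normal,not_assessable,not_assessable
FIX007,elevated,elevated,elevated,normal,not_assessable,not_assessable
FIX008,elevated,elevated,elevated,normal,not_assessable,not_assessable
FIX009,normal,normal,normal,normal,not_assessable,not_assessable
FIX010,normal,normal,normal,normal,not_assessable,not_assessable
FIX011,normal,normal,normal,normal,not_assessable,not_assessable
FIX012,elevated,elevated,elevated,elevated,normal,normal
FIX013,elevated,elevated,elevated,elevated,normal,normal
FIX014,elevated,elevated,elevated,elevated,normal,normal
FIX015,elevated,elevated,elevated,elevated,dysfunction,dysfunction
FIX016,elevated,elevated,elevated,elevated,dysfunction,dysfunction
FIX017,elevated,elevated,elevated,elevated,dysfunction,dysfunction
FIX018,not_assessable,not_assessable,not_assessable,not_assessable,dysfunction,dysfunction
FIX019,not_assessable,not_assessable,not_assessable,not_assessable,dysfunction,dysfunction
FIX020,not_assessable,not_assessable,not_assessable,not_assessable,dysfunction,dysfunction
FIX021,normal,normal,normal,normal,indeterminate,normal
FIX022,normal,normal,normal,normal,indeterminate,normal
FIX023,normal,normal,normal,normal,indeterminate,normal
FIX024,elevated,elevated,elevated,elevated,dysfunction,dysfunction
FIX025,elevated,elevated,elevated,elevated,dysfunction,dysfunction
FIX026,elevated,elevated,elevated,elevated,dysfunction,dysfunction
FIX027,elevated,elevated,elevated,elevated,not_assessable,not_assessable
FIX028,elevated,elevated,elevated,elevated,not_assessable,not_assessable
FIX029,elevated,elevated,elevated,elevated,not_assessable,not_assessable
FIX030,indeterminate,elevated,elevated,normal,not_assessable,not_assessable
FIX031,indeterminate,elevated,elevated,normal,not_assessable,not_assessable
FIX032,indeterminate,elevated,elevated,normal,not_assessable,not_assessable
FIX033,indeterminate,normal,normal,normal,not_assessable,not_assessable
FIX034,indeterminate,normal,normal,normal,not_assessable,not_assessable
FIX035,indeterminate,normal,normal,normal,not_assessable,not_assessable
FIX036,indeterminate,indeterminate,indeterminate,indeterminate,not_assessable,not_assessable
FIX037,indeterminate,indeterminate,indeterminate,indeterminate,not_assessable,not_assessable
FIX038,indeterminate,indeterminate,indeterminate,indeterminate,not_assessable,not_assessable
FIX039,indeterminate,indeterminate,indeterminate,indeterminate,not_assessable,not_assessable
FIX040,indeterminate,indeterminate,indeterminate,indeterminate,not_assessable,not_assessable
FIX041,indeterminate,indeterminate,indeterminate,indeterminate,not_assessable,not_assessable
FIX042,indeterminate,elevated,indeterminate,indeterminate,not_assessable,not_assessable
FIX043,indeterminate,elevated,indeterminate,indeterminate,not_assessable,not_assessable
FIX044,indeterminate,elevated,indeterminate,indeterminate,not_assessable,not_assessable
FIX045,normal,normal,normal,normal,normal,normal
FIX046,normal,normal,normal,normal,normal,normal
FIX047,normal,normal,normal,normal,normal,normal
FIX048,elevated,normal,elevated,normal,dysfunction,dysfunction
FIX049,elevated,normal,elevated,normal,dysfunction,dysfunction
FIX050,elevated,normal,elevated,normal,dysfunction,dysfunction
FIX051,normal,elevated,normal,normal,indeterminate,dysfunction
FIX052,normal,elevated,normal,normal,indeterminate,dysfunction
FIX053,normal,elevated,normal,normal,indeterminate,dysfunction
FIX054,indeterminate,indeterminate,indeterminate,indeterminate,not_assessable,not_assessable
FIX055,indeterminate,indeterminate,indeterminate,indeterminate,not_assessable,not_assessable
FIX056,indeterminate,indeterminate,indeterminate,indeterminate,not_assessable,not_assessable
FIX057,elevated,elevated,elevated,elevated,dysfunction,dysfunction
FIX058,elevated,elevated,elevated,elevated,dysfunction,dysfunction
FIX059,elevated,elevated,elevated,elevated,dysfunction,dysfunction
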