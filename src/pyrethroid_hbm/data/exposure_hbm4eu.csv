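study_id,country,population,biomarker,n,p05,p50,p95,p95_lcl,p95_ucl,note
BE-3xG,Belgium,children,3-PBA,,0.39,1.69,7.05,,,transcribed 95th percentile
BE-3xG,Belgium,children,DCCA,,,,7.52,,,stored as 7.52 (also printed as 7.5 elsewhere)
BE-3xG,Belgium,children,ClF3CA,,,,0.774,,,back-calculated from printed RCR 0.086 x GV 9
BE-3xG,Belgium,children,DBCA,,,,3.06,,,back-calculated from printed RCR 0.034 x GV 90
BE-3xG,Belgium,children,4-FPBA,,,,NR,,,low detection frequency
CY-ORGANIKO,Cyprus,children,3-PBA,,,,6.34,,,back-calculated from printed screening RCR 1.95 x 3.25
CY-ORGANIKO,Cyprus,children,ClF3CA,,,,0.261,,,back-calculated from printed RCR 0.029 x GV 9
CY-ORGANIKO,Cyprus,children,DBCA,,,,3.96,,,back-calculated from printed RCR 0.044 x GV 90
CY-ORGANIKO,Cyprus,children,DCCA,,,,6.0,,,back-calculated from printed RCR 0.20 x GV 30
CY-ORGANIKO,Cyprus,children,4-FPBA,,,,NR,,,low detection frequency
FR-ESTEBAN,France,children,3-PBA,,,,4.26,,,synthetic plausible value; not printed
FR-ESTEBAN,France,children,DBCA,,,,5.32,,,transcribed 95th percentile
FR-ESTEBAN,France,children,DCCA,,,,3.24,,,back-calculated from printed RCR 0.108 x GV 30 (text prints 3.2)
FR-ESTEBAN,France,children,4-FPBA,,,,0.06,,,back-calculated from printed RCR 0.004 x screening 16
IL-RAVMABAT,Israel,children,3-PBA,,,,4.69,,,back-calculated from 21%-scenario RCR 0.33 x 14.2
IL-RAVMABAT,Israel,children,ClF3CA,,,,0.765,,,back-calculated from printed RCR 0.085 x GV 9
IL-RAVMABAT,Israel,children,DBCA,,,,0.99,,,back-calculated from printed RCR 0.011 x GV 90
IL-RAVMABAT,Israel,children,DCCA,,,,5.1,,,back-calculated from printed RCR 0.17 x GV 30
IL-RAVMABAT,Israel,children,4-FPBA,,,,0.21,,,back-calculated from printed RCR 0.013 x screening 16
SI-SLOCRP,Slovenia,children,3-PBA,,,,3.72,,,transcribed 95th percentile
SI-SLOCRP,Slovenia,children,ClF3CA,,,,NR,,,low detection frequency
SI-SLOCRP,Slovenia,children,DBCA,,,,NR,,,low detection frequency
SI-SLOCRP,Slovenia,children,DCCA,,,,NR,,,low detection frequency
SI-SLOCRP,Slovenia,children,4-FPBA,,,,0.29,,,transcribed 95th percentile
NL-SPECIMEN,Netherlands,children,3-PBA,,,,5.0,,,synthetic plausible value; not printed
NL-SPECIMEN,Netherlands,children,ClF3CA,,,,1.28,,,transcribed 95th percentile
NL-SPECIMEN,Netherlands,children,DBCA,,,,3.78,,,back-calculated from printed RCR 0.042 x GV 90
NL-SPECIMEN,Netherlands,children,DCCA,,,,4.5,,,back-calculated from printed RCR 0.15 x GV 30
NL-SPECIMEN,Netherlands,children,4-FPBA,,,,NR,,,low detection frequency
DE-ESB,Germany,adults,3-PBA,,,,1.6,,,synthetic plausible value; not printed
DE-ESB,Germany,adults,ClF3CA,,,,0.266,,,back-calculated from printed RCR 0.019 x GV 14
DE-ESB,Germany,adults,DBCA,,,,0.533,,,back-calculated from printed RCR 0.0041 x GV 130
DE-ESB,Germany,adults,DCCA,,,,0.85,,,transcribed 95th percentile
DE-ESB,Germany,adults,4-FPBA,,,,NR,,,low detection frequency
FR-ESTEBAN,France,adults,3-PBA,,,,2.4,,,synthetic plausible value; not printed
FR-ESTEBAN,France,adults,DBCA,,,,5.37,,,transcribed 95th percentile
FR-ESTEBAN,France,adults,DCCA,,,,2.39,,,back-calculated from printed RCR 0.053 x GV 45
FR-ESTEBAN,France,adults,4-FPBA,,,,0.07,,,transcribed 95th percentile
CH-HBM4EU,Switzerland,adults,3-PBA,,,,2.0,,,synthetic plausible value; not printed
CH-HBM4EU,Switzerland,adults,ClF3CA,,,,0.434,,,back-calculated from printed RCR 0.031 x GV 14
CH-HBM4EU,Switzerland,adults,DBCA,,,,0.884,,,back-calculated from printed RCR 0.0068 x GV 130
CH-HBM4EU,Switzerland,adults,DCCA,,,,1.62,,,back-calculated from printed RCR 0.036 x GV 45
CH-HBM4EU,Switzerland,adults,4-FPBA,,,,NR,,,low detection frequency
IL-RAVMABAT,Israel,adults,3-PBA,,,,2.87,,,transcribed 95th percentile (highest adult value)
IL-RAVMABAT,Israel,adults,3-PBA+4-FPBA,,,,3.13,,,reported sum percentile (maximum for adults)
IL-RAVMABAT,Israel,adults,ClF3CA,,,,1.05,,,transcribed 95th percentile
IL-RAVMABAT,Israel,adults,DBCA,,,,0.416,,,back-calculated from printed RCR 0.0032 x GV 130
IL-RAVMABAT,Israel,adults,DCCA,,,,3.08,,,transcribed 95th percentile
IL-RAVMABAT,Israel,adults,4-FPBA,,,,NR,,,low detection frequency
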