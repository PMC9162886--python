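device_id,name,description,comparator,real_price,real_price_currency,cea_available,gain,outcome_kind,cost_b,cost_b_currency,othercosts_a,othercosts_a_currency,time_horizon_months,source,source_kind
neovasc_reducer,Neovasc Reducer (EPS Vascular),coronary sinus reducer stent,before-after comparison in included patients,6500,EUR,true,0.138,QALY,6988,EUR,8702,EUR,12,Gallone 2020,CEA_registry
amds,Ascyrus Medical Dissection Stent (CryoLife),hybrid aortic system for dissections,standard of care,13000,EUR,true,0.048,life_year,0,EUR,0,EUR,12,Bozso 2021; Pape 2015,HTA_report
cardioband,Cardioband (Edwards Lifesciences),tricuspid valve reconstruction system,standard of care,22000,EUR,true,0.13,life_year,0,EUR,0,EUR,12,Taramasso 2019,HTA_report
pascal,Pascal Mitral Ace (Edwards Lifesciences),mitral valve transcatheter repair system,standard of care,22000,EUR,true,1.07,QALY,10704,GBP,26471,GBP,lifetime,Shore 2021,HTA_report
cardia_ultrasept,Cardia Ultrasept Dia (Cardia Inc.),atrial septal defect closure device,surgical closure,4243,EUR,true,0.03,QALY,16000,BRL,6836,BRL,lifetime,Costa 2014,CEA_registry
placeholder_06,synthetic placeholder device 6,synthetic stand-in for a screened-out device without published CEA,standard of care,3200,EUR,false,,,,,,,,,
placeholder_07,synthetic placeholder device 7,synthetic stand-in for a screened-out device without published CEA,standard of care,5400,EUR,false,,,,,,,,,
placeholder_08,synthetic placeholder device 8,synthetic stand-in for a screened-out device without published CEA,standard of care,1850,EUR,false,,,,,,,,,
placeholder_09,synthetic placeholder device 9,synthetic stand-in for a screened-out device without published CEA,standard of care,12500,EUR,false,,,,,,,,,
placeholder_10,synthetic placeholder device 10,synthetic stand-in for a screened-out device without published CEA,standard of care,7600,EUR,false,,,,,,,,,
placeholder_11,synthetic placeholder device 11,synthetic stand-in for a screened-out device without published CEA,standard of care,950,EUR,false,,,,,,,,,
placeholder_12,synthetic placeholder device 12,synthetic stand-in for a screened-out device without published CEA,standard of care,20400,EUR,false,,,,,,,,,
placeholder_13,synthetic placeholder device 13,synthetic stand-in for a screened-out device without published CEA,standard of care,4100,EUR,false,,,,,,,,,
placeholder_14,synthetic placeholder device 14,synthetic stand-in for a screened-out device without published CEA,standard of care,15800,EUR,false,,,,,,,,,
placeholder_15,synthetic placeholder device 15,synthetic stand-in for a screened-out device without published CEA,standard of care,2700,EUR,false,,,,,,,,,
placeholder_16,synthetic placeholder device 16,synthetic stand-in for a screened-out device without published CEA,standard of care,8900,EUR,false,,,,,,,,,
placeholder_17,synthetic placeholder device 17,synthetic stand-in for a screened-out device without published CEA,standard of care,6100,EUR,false,,,,,,,,,
placeholder_18,synthetic placeholder device 18,synthetic stand-in for a screened-out device without published CEA,standard of care,30500,EUR,false,,,,,,,,,
placeholder_19,synthetic placeholder device 19,synthetic stand-in for a screened-out device without published CEA,standard of care,1450,EUR,false,,,,,,,,,
placeholder_20,synthetic placeholder device 20,synthetic stand-in for a screened-out device without published CEA,standard of care,9800,EUR,false,,,,,,,,,
placeholder_21,synthetic placeholder device 21,synthetic stand-in for a screened-out device without published CEA,standard of care,5200,EUR,false,,,,,,,,,
placeholder_22,synthetic placeholder device 22,synthetic stand-in for a screened-out device without published CEA,standard of care,17300,EUR,false,,,,,,,,,
placeholder_23,synthetic placeholder device 23,synthetic stand-in for a screened-out device without published CEA,standard of care,2350,EUR,false,,,,,,,,,
placeholder_24,synthetic placeholder device 24,synthetic stand-in for a screened-out device without published CEA,standard of care,11200,EUR,false,,,,,,,,,
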