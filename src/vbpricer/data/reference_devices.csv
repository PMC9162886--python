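device_id,name,description,comparator,real_price,real_price_currency,cea_available,gain,outcome_kind,cost_b,cost_b_currency,othercosts_a,othercosts_a_currency,time_horizon_months,source,source_kind
neovasc_reducer,Neovasc Reducer (EPS Vascular),coronary sinus reducer stent,before-after comparison in included patients,6500,EUR,true,0.138,QALY,6988,EUR,8702,EUR,12,Gallone 2020,CEA_registry
amds,Ascyrus Medical Dissection Stent (CryoLife),hybrid aortic system for dissections,standard of care,13000,EUR,true,0.048,life_year,0,EUR,0,EUR,12,Bozso 2021; Pape 2015,HTA_report
cardioband,Cardioband (Edwards Lifesciences),tricuspid valve reconstruction system,standard of care,22000,EUR,true,0.13,life_year,0,EUR,0,EUR,12,Taramasso 2019,HTA_report
pascal,Pascal Mitral Ace (Edwards Lifesciences),mitral valve transcatheter repair system,standard of care,22000,EUR,true,1.07,QALY,10704,GBP,26471,GBP,lifetime,Shore 2021,HTA_report
cardia_ultrasept,Cardia Ultrasept Dia (Cardia Inc.),atrial septal defect closure device,surgical closure,4243,EUR,true,0.03,QALY,16000,BRL,6836,BRL,lifetime,Costa 2014,CEA_registry
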