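company,brand,year,users_millions,sticks_billions,report_vintage,notes
PMI,IQOS,2014,N/A,N/A,,
PMI,IQOS,2015,N/A,N/A,,
PMI,IQOS,2016,2.1,7.4,,
PMI,IQOS,2017,6.9,36.2,,
PMI,IQOS,2018,9.6,41.4,,
PMI,IQOS,2019,13.6,59.7,,
PMI,IQOS,2020,17.6,76.1,,
PMI,IQOS,2021,21.2,95.0,,From 2021 totals include licensed KT&G products outside South Korea
PMI,IQOS,2022,24.9,109.2,,
PMI,IQOS,2023,28.6,125.3,,
PMI,IQOS,2024,32.2,139.7,,Users defined as adults using PMI HTPs in past 7 days
KT&G,lil,2014,0.0,0.0,,
KT&G,lil,2015,0.0,0.0,,
KT&G,lil,2016,0.0,0.0,,
KT&G,lil,2017,N/A,0.0,,
KT&G,lil,2018,N/A,1.2,,
KT&G,lil,2019,N/A,2.5,,
KT&G,lil,2020,N/A,1.5,,Domestic/international split not reported
KT&G,lil,2021,N/A,3.7,,Domestic (South Korea) shipments
KT&G,lil,2022,N/A,5.8,,Domestic (South Korea) shipments
KT&G,lil,2023,N/A,8.2,,Domestic (South Korea) shipments
KT&G,lil,2024,N/A,8.3,,Domestic (South Korea) shipments
BAT,glo,2014,0.0,0.0,,
BAT,glo,2015,0.0,0.0,,
BAT,glo,2016,N/A,N/A,,glo launched December 2016
BAT,glo,2017,N/A,2.2,,
BAT,glo,2018,N/A,7.0,,
BAT,glo,2019,3.0,9.0,,No formal user definition published
BAT,glo,2020,4.0,11.0,,
BAT,glo,2021,6.8,19.0,,
BAT,glo,2022,7.2,24.0,,
BAT,glo,2023,8.6,24.0,,
BAT,glo,2024,10.2,21.0,,
JT,Ploom,2014,0.0,0.0,,
JT,Ploom,2015,0.0,0.0,,
JT,Ploom,2016,0.0,0.0,,
JT,Ploom,2017,0.0,0.0,,
JT,Ploom,2018,0.0,0.0,,
JT,Ploom,2019,N/A,N/A,,
JT,Ploom,2020,N/A,N/A,,
JT,Ploom,2021,N/A,3.0,,
JT,Ploom,2022,N/A,6.7,,
JT,Ploom,2023,N/A,11.1,,
JT,Ploom,2024,N/A,14.1,,
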