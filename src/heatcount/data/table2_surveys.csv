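country,prevalence_pct,year,survey,cohort,population_thousands,users_printed
Austria,3.00,2023,Eurobarometer,15+,7764.2,232927
Belarus,3.00,2020,STEPS,18+,7571.0,227131
Belgium,1.00,2023,Eurobarometer,15+,9717.5,97175
Bulgaria,2.00,2023,Eurobarometer,15+,5833.4,116669
Croatia,2.00,2023,Eurobarometer,15+,3348.3,66966
Cyprus,5.00,2023,Eurobarometer,15+,1117.9,55895
Czechia,4.00,2023,Eurobarometer,15+,8971.1,358843
Estonia,2.00,2023,Eurobarometer,15+,1130.9,22619
Georgia,1.60,2021,Local,18+,2873.7,45980
Germany,1.00,2023,Eurobarometer,15+,72387.7,723877
Greece,3.00,2023,Eurobarometer,15+,8970.5,269116
Hungary,3.00,2023,Eurobarometer,15+,8275.2,248255
Ireland,1.00,2023,Eurobarometer,15+,4115.8,41158
Italy,4.00,2023,Eurobarometer,15+,52232.4,2089297
Japan,11.80,2022,Local,16-74,90240.2,10648339
Jordan,4.10,2025,Local,15+,7670.8,314503
Latvia,3.00,2023,Eurobarometer,15+,1581.5,47445
Lithuania,5.00,2023,Eurobarometer,15+,2393.0,119650
Luxembourg,1.00,2023,Eurobarometer,15+,549.6,5496
Netherlands,1.00,2023,Eurobarometer,15+,15155.9,151559
Philippines,0.10,2021,GATS,15+,77692.2,77692
Poland,1.00,2023,Eurobarometer,15+,32503.6,325036
Portugal,5.00,2023,Eurobarometer,15+,9062.6,453131
Romania,2.00,2023,Eurobarometer,15+,16097.0,321941
Slovakia,4.00,2023,Eurobarometer,15+,4599.2,183969
Slovenia,2.00,2023,Eurobarometer,15+,1795.9,35918
South Korea,5.90,2022,Local,19+,44374.2,2618081
Spain,1.00,2023,Eurobarometer,15+,41325.7,413257
Mexico,0.20,2023,GATS,15+,96059.4,192119
Costa Rica,0.04,2022,GATS,15+,4033.0,1613
Ukraine,3.00,2023,Local,18+,33723.9,1011717
Moldova,2.60,2021,STEPS,18+,2354.7,61223
Kazakhstan,1.00,2019,GATS,15+,13478.2,134782
Armenia,0.80,2022,Local,15+,2294.9,18359
Uzbekistan,0.24,2019,STEPS,18+,21492.9,50508
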