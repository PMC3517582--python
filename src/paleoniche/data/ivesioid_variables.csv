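variable,mean_auc,selected
Mean_temperature,0.96,False
Mean_temperature_in_warmest_month,0.9,False
Mean_temperature_in_coolest_month,0.97,True
Standard_deviation_of_mean_temperature,0.88,True
Mean_daily_precipitation,0.8,False
Mean_daily_precipitation_in_wettest_month,0.8,False
Mean_daily_precipitation_in_warmest_month,0.87,True
Mean_daily_precipitation_in_driest_month,0.81,False
Mean_daily_precipitation_in_coolest_month,0.9,True
Standard_deviation_of_mean_precipitation,0.83,False
Mean_daily_precipitation_in_coolest_quarter,0.87,False
Mean_daily_precipitation_in_driest_quarter,0.8,False
Mean_daily_precipitation_in_warmest_quarter,0.86,False
Mean_daily_precipitation_in_wettest_quarter,0.8,False
Mean_temperature_in_coolest_quarter,0.97,False
Mean_temperature_in_warmest_quarter,0.91,False
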