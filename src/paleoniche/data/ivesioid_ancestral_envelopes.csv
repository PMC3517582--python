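node,variable,min,max
40,Standard_deviation_of_mean_temperature,7.1,10.3
40,Mean_daily_precipitation_in_warmest_month,0.1,1.3
40,Mean_daily_precipitation_in_coolest_month,0.1,5.5
40,Mean_temperature_in_coolest_month,-5.0,3.6
41,Standard_deviation_of_mean_temperature,7.4,9.8
41,Mean_daily_precipitation_in_warmest_month,0.1,0.6
41,Mean_daily_precipitation_in_coolest_month,0.1,4.8
41,Mean_temperature_in_coolest_month,-3.3,2.8
42,Standard_deviation_of_mean_temperature,7.2,9.7
42,Mean_daily_precipitation_in_warmest_month,0.1,0.5
42,Mean_daily_precipitation_in_coolest_month,0.1,4.8
42,Mean_temperature_in_coolest_month,-2.9,2.5
43,Standard_deviation_of_mean_temperature,6.9,9.4
43,Mean_daily_precipitation_in_warmest_month,0.1,0.4
43,Mean_daily_precipitation_in_coolest_month,0.1,4.7
43,Mean_temperature_in_coolest_month,-1.7,3.0
44,Standard_deviation_of_mean_temperature,6.6,9.3
44,Mean_daily_precipitation_in_warmest_month,0.1,0.4
44,Mean_daily_precipitation_in_coolest_month,0.1,5.0
44,Mean_temperature_in_coolest_month,-1.5,3.2
45,Standard_deviation_of_mean_temperature,6.4,9.2
45,Mean_daily_precipitation_in_warmest_month,0.1,0.4
45,Mean_daily_precipitation_in_coolest_month,0.1,5.1
45,Mean_temperature_in_coolest_month,-1.3,3.4
46,Standard_deviation_of_mean_temperature,6.3,9.1
46,Mean_daily_precipitation_in_warmest_month,0.1,0.4
46,Mean_daily_precipitation_in_coolest_month,0.1,5.2
46,Mean_temperature_in_coolest_month,-1.3,3.4
47,Standard_deviation_of_mean_temperature,6.3,8.9
47,Mean_daily_precipitation_in_warmest_month,0.1,0.3
47,Mean_daily_precipitation_in_coolest_month,0.1,5.2
47,Mean_temperature_in_coolest_month,-1.2,3.1
48,Standard_deviation_of_mean_temperature,6.9,8.5
48,Mean_daily_precipitation_in_warmest_month,0.1,0.2
48,Mean_daily_precipitation_in_coolest_month,0.1,4.7
48,Mean_temperature_in_coolest_month,-1.1,2.0
49,Standard_deviation_of_mean_temperature,7.1,8.9
49,Mean_daily_precipitation_in_warmest_month,0.1,0.1
49,Mean_daily_precipitation_in_coolest_month,0.1,4.6
49,Mean_temperature_in_coolest_month,-1.7,1.4
50,Standard_deviation_of_mean_temperature,5.8,8.9
50,Mean_daily_precipitation_in_warmest_month,0.1,0.3
50,Mean_daily_precipitation_in_coolest_month,0.1,5.9
50,Mean_temperature_in_coolest_month,-0.9,3.5
51,Standard_deviation_of_mean_temperature,7.6,9.6
51,Mean_daily_precipitation_in_warmest_month,0.1,0.3
51,Mean_daily_precipitation_in_coolest_month,0.1,5.3
51,Mean_temperature_in_coolest_month,-4.1,0.0
52,Standard_deviation_of_mean_temperature,6.2,9.1
52,Mean_daily_precipitation_in_warmest_month,0.1,0.4
52,Mean_daily_precipitation_in_coolest_month,0.1,5.3
52,Mean_temperature_in_coolest_month,-1.4,3.6
53,Standard_deviation_of_mean_temperature,5.5,9.0
53,Mean_daily_precipitation_in_warmest_month,0.1,0.5
53,Mean_daily_precipitation_in_coolest_month,0.1,5.4
53,Mean_temperature_in_coolest_month,-1.7,4.6
54,Standard_deviation_of_mean_temperature,4.3,9.1
54,Mean_daily_precipitation_in_warmest_month,0.1,0.4
54,Mean_daily_precipitation_in_coolest_month,0.1,5.2
54,Mean_temperature_in_coolest_month,0.4,7.5
55,Standard_deviation_of_mean_temperature,4.6,9.0
55,Mean_daily_precipitation_in_warmest_month,0.0,0.4
55,Mean_daily_precipitation_in_coolest_month,0.0,3.6
55,Mean_temperature_in_coolest_month,2.3,8.5
56,Standard_deviation_of_mean_temperature,5.9,8.7
56,Mean_daily_precipitation_in_warmest_month,0.0,0.2
56,Mean_daily_precipitation_in_coolest_month,0.0,2.7
56,Mean_temperature_in_coolest_month,2.4,7.2
57,Standard_deviation_of_mean_temperature,6.3,9.0
57,Mean_daily_precipitation_in_warmest_month,0.1,0.4
57,Mean_daily_precipitation_in_coolest_month,0.1,5.8
57,Mean_temperature_in_coolest_month,-1.4,3.5
58,Standard_deviation_of_mean_temperature,5.7,8.8
58,Mean_daily_precipitation_in_warmest_month,0.0,0.3
58,Mean_daily_precipitation_in_coolest_month,0.0,4.6
58,Mean_temperature_in_coolest_month,2.7,6.6
59,Standard_deviation_of_mean_temperature,6.4,8.9
59,Mean_daily_precipitation_in_warmest_month,0.1,0.4
59,Mean_daily_precipitation_in_coolest_month,0.1,6.3
59,Mean_temperature_in_coolest_month,-2.2,2.8
60,Standard_deviation_of_mean_temperature,6.0,8.5
60,Mean_daily_precipitation_in_warmest_month,0.1,0.3
60,Mean_daily_precipitation_in_coolest_month,0.1,7.8
60,Mean_temperature_in_coolest_month,-2.3,2.8
61,Standard_deviation_of_mean_temperature,6.8,9.1
61,Mean_daily_precipitation_in_warmest_month,0.1,0.3
61,Mean_daily_precipitation_in_coolest_month,0.1,6.3
61,Mean_temperature_in_coolest_month,-3.2,1.9
62,Standard_deviation_of_mean_temperature,6.8,9.0
62,Mean_daily_precipitation_in_warmest_month,0.1,0.3
62,Mean_daily_precipitation_in_coolest_month,0.1,6.5
62,Mean_temperature_in_coolest_month,-3.0,2.0
63,Standard_deviation_of_mean_temperature,7.5,9.3
63,Mean_daily_precipitation_in_warmest_month,0.1,0.4
63,Mean_daily_precipitation_in_coolest_month,0.1,6.0
63,Mean_temperature_in_coolest_month,-4.9,0.5
64,Standard_deviation_of_mean_temperature,7.4,9.5
64,Mean_daily_precipitation_in_warmest_month,0.1,0.5
64,Mean_daily_precipitation_in_coolest_month,0.1,6.5
64,Mean_temperature_in_coolest_month,-5.5,0.8
65,Standard_deviation_of_mean_temperature,8.1,9.4
65,Mean_daily_precipitation_in_warmest_month,0.2,0.4
65,Mean_daily_precipitation_in_coolest_month,0.2,5.3
65,Mean_temperature_in_coolest_month,-5.8,-1.1
66,Standard_deviation_of_mean_temperature,5.0,8.7
66,Mean_daily_precipitation_in_warmest_month,0.1,0.4
66,Mean_daily_precipitation_in_coolest_month,0.1,4.7
66,Mean_temperature_in_coolest_month,2.5,6.8
67,Standard_deviation_of_mean_temperature,6.1,9.2
67,Mean_daily_precipitation_in_warmest_month,0.1,0.3
67,Mean_daily_precipitation_in_coolest_month,0.1,2.7
67,Mean_temperature_in_coolest_month,3.3,6.7
68,Standard_deviation_of_mean_temperature,7.7,9.7
68,Mean_daily_precipitation_in_warmest_month,0.1,0.5
68,Mean_daily_precipitation_in_coolest_month,0.1,4.4
68,Mean_temperature_in_coolest_month,-2.9,2.7
69,Standard_deviation_of_mean_temperature,7.7,9.4
69,Mean_daily_precipitation_in_warmest_month,0.1,0.3
69,Mean_daily_precipitation_in_coolest_month,0.1,4.6
69,Mean_temperature_in_coolest_month,-2.1,3.3
70,Standard_deviation_of_mean_temperature,7.8,9.2
70,Mean_daily_precipitation_in_warmest_month,0.1,0.3
70,Mean_daily_precipitation_in_coolest_month,0.1,4.7
70,Mean_temperature_in_coolest_month,-1.4,3.3
71,Standard_deviation_of_mean_temperature,8.1,10.0
71,Mean_daily_precipitation_in_warmest_month,0.1,0.4
71,Mean_daily_precipitation_in_coolest_month,0.1,3.7
71,Mean_temperature_in_coolest_month,-3.1,2.2
72,Standard_deviation_of_mean_temperature,7.5,9.8
72,Mean_daily_precipitation_in_warmest_month,0.1,0.2
72,Mean_daily_precipitation_in_coolest_month,0.1,4.2
72,Mean_temperature_in_coolest_month,-1.9,3.8
73,Standard_deviation_of_mean_temperature,7.2,9.5
73,Mean_daily_precipitation_in_warmest_month,0.1,0.1
73,Mean_daily_precipitation_in_coolest_month,0.1,4.6
73,Mean_temperature_in_coolest_month,-1.5,3.3
74,Standard_deviation_of_mean_temperature,8.7,10.2
74,Mean_daily_precipitation_in_warmest_month,0.1,0.4
74,Mean_daily_precipitation_in_coolest_month,0.1,3.0
74,Mean_temperature_in_coolest_month,-3.9,0.8
75,Standard_deviation_of_mean_temperature,8.9,10.2
75,Mean_daily_precipitation_in_warmest_month,0.2,0.4
75,Mean_daily_precipitation_in_coolest_month,0.2,2.8
75,Mean_temperature_in_coolest_month,-3.8,0.5
76,Standard_deviation_of_mean_temperature,8.8,10.3
76,Mean_daily_precipitation_in_warmest_month,0.2,0.4
76,Mean_daily_precipitation_in_coolest_month,0.2,2.8
76,Mean_temperature_in_coolest_month,-4.1,0.3
77,Standard_deviation_of_mean_temperature,8.6,10.2
77,Mean_daily_precipitation_in_warmest_month,0.1,0.3
77,Mean_daily_precipitation_in_coolest_month,0.1,3.0
77,Mean_temperature_in_coolest_month,-4.5,-0.3
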