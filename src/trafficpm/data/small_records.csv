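study_id,city,country,region,pub_year,population,latitude,longitude,site_type,overall_pm25,traffic_share_pct,sea_salt_reported,method
S001,city_022,Iran,Middle East,2006,1952799,40.8132,-102.3418,urban,61.2113,18.2346,1,PMF
S001,city_003,Brazil,South/Central America,2014,6422141,-19.4992,68.3674,urban,25.5245,39.9516,0,PMF
S002,city_018,Spain,Southwestern Europe,2009,995936,29.7852,44.911,urban,19.6306,26.2599,1,PMF
S002,city_002,China,East Asia,2007,8246068,7.349,106.7968,urban,57.99,29.836,0,PMF
S003,city_010,China,East Asia,2010,10810864,45.6981,-166.8281,urban,44.2957,41.2279,1,CMB
S003,city_001,China,East Asia,2011,2692025,2.5565,98.425,urban,32.7152,41.2854,0,PMF
S004,city_016,China,East Asia,2012,252726,51.5829,114.8879,urban,91.5547,14.0198,1,PMF
S004,city_021,India,Southern Asia,2001,630045,-2.5342,162.2891,urban,31.384,45.508,1,PMF
S005,city_020,Spain,Southwestern Europe,2006,1006624,34.0129,-51.9736,urban,35.7585,35.0482,1,PMF
S005,city_008,China,East Asia,2014,106758,52.0699,-35.9988,urban,69.1896,11.4082,0,CMB
S006,city_026,China,East Asia,2010,2565491,20.6527,41.1688,urban,42.9947,28.7564,1,PMF
S006,city_005,United States,North America,2007,115479,-20.5141,-177.3276,urban,3.5709,26.9228,1,PCA
S007,city_003,Brazil,South/Central America,1989,6422141,-19.4992,68.3674,urban,37.3106,83.7269,0,CMB
S007,city_020,Spain,Southwestern Europe,2011,1006624,34.0129,-51.9736,urban,31.3398,42.7344,1,CMB
S008,city_017,United States,North America,2012,1019152,13.2414,-36.5616,urban,11.0908,10.5211,0,PMF
S008,city_023,China,East Asia,2014,457846,24.5995,112.561,urban,41.4958,20.7282,1,CMB
S009,city_027,United States,North America,2009,2564595,34.548,4.6705,urban,16.9912,27.7204,1,CMB
S009,city_020,Spain,Southwestern Europe,1999,1006624,34.0129,-51.9736,urban,63.6114,34.2495,1,PMF
S010,city_013,Brazil,South/Central America,1999,200523,50.4984,-108.8102,urban,72.974,32.8353,0,PMF
S010,city_028,India,Southern Asia,2010,199321,-9.1217,-130.4695,urban,20.6742,37.2228,0,PMF
S011,city_008,China,East Asia,2010,106758,52.0699,-35.9988,urban,48.3578,11.6104,1,PMF
S011,city_018,Spain,Southwestern Europe,2011,995936,29.7852,44.911,urban,15.5943,45.615,1,PMF
S012,city_017,United States,North America,2014,1019152,13.2414,-36.5616,urban,12.2637,15.7919,0,CMB
S012,city_028,India,Southern Asia,2009,199321,-9.1217,-130.4695,urban,15.8755,20.4559,0,CMB
S013,city_000,United Kingdom,Northwestern Europe,2012,3182427,15.5108,21.9572,urban,10.3107,20.7598,0,PMF
S013,city_015,United States,North America,2005,2913562,17.0293,49.1248,urban,15.9558,41.8367,0,CMB
S014,city_021,India,Southern Asia,2008,630045,-2.5342,162.2891,urban,37.8629,14.4021,0,PMF
S014,city_016,China,East Asia,2012,252726,51.5829,114.8879,urban,53.4768,18.7105,0,PMF
S015,city_027,United States,North America,2006,2564595,34.548,4.6705,urban,39.1904,17.3986,0,PMF
S015,city_013,Brazil,South/Central America,2006,200523,50.4984,-108.8102,urban,57.041,15.1003,1,CMB
S016,city_024,Germany,Western Europe,1997,242703,42.4221,-85.8252,urban,16.0993,13.7442,0,PCA
S016,city_025,India,Southern Asia,2008,805802,39.7033,119.9099,urban,39.6578,30.4258,1,CMB
S017,city_014,Spain,Southwestern Europe,2010,1133371,-8.8213,52.7689,urban,19.2721,58.7435,1,CMB
S017,city_011,Germany,Western Europe,2012,761217,22.1991,-25.9051,urban,8.0119,10.9478,0,PCA
S018,city_016,China,East Asia,2012,252726,51.5829,114.8879,urban,54.1028,12.1376,0,CMB
S018,city_003,Brazil,South/Central America,2011,6422141,-19.4992,68.3674,urban,30.7111,42.2025,0,PMF
S019,city_004,United Kingdom,Northwestern Europe,2006,31560,22.0521,-64.5027,urban,6.5561,10.4426,1,PCA
S019,city_029,Australia,Oceania/Japan,2003,375796,55.0594,140.7474,urban,21.7249,12.0442,1,PCA
S020,city_007,Spain,Southwestern Europe,2008,11084761,40.7411,-17.5257,urban,49.9625,28.6994,0,CMB
S020,city_006,India,Southern Asia,1996,9484289,30.9586,-171.2716,urban,41.1142,24.5018,0,PMF
S021,city_009,United States,North America,2009,139728,16.0771,70.7825,urban,4.0028,17.6494,1,CMB
S021,city_019,Australia,Oceania/Japan,2012,783347,19.6896,-9.391,urban,14.7142,18.645,1,CMB
S022,city_002,China,East Asia,1988,8246068,7.349,106.7968,urban,53.6822,22.5936,0,PMF
S022,city_029,Australia,Oceania/Japan,2006,375796,55.0594,140.7474,urban,24.2132,13.5915,0,PMF
S023,city_017,United States,North America,2012,1019152,13.2414,-36.5616,urban,9.3998,15.2113,0,PMF
S023,city_011,Germany,Western Europe,1992,761217,22.1991,-25.9051,urban,11.5169,33.0198,0,PMF
S024,city_011,Germany,Western Europe,2007,761217,22.1991,-25.9051,urban,9.3296,15.619,1,CMB
S024,city_028,India,Southern Asia,2010,199321,-9.1217,-130.4695,urban,37.3003,27.3104,1,CMB
S025,city_012,United States,North America,2013,363877,12.1202,50.416,urban,21.3276,14.9521,0,PMF
S025,city_023,China,East Asia,2009,457846,24.5995,112.561,urban,37.2397,19.5139,1,PMF
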