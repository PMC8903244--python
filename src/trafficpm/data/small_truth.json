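{
 "city": [
  "city_022",
  "city_003",
  "city_018",
  "city_002",
  "city_010",
  "city_001",
  "city_016",
  "city_021",
  "city_020",
  "city_008",
  "city_026",
  "city_005",
  "city_003",
  "city_020",
  "city_017",
  "city_023",
  "city_027",
  "city_020",
  "city_013",
  "city_028",
  "city_008",
  "city_018",
  "city_017",
  "city_028",
  "city_000",
  "city_015",
  "city_021",
  "city_016",
  "city_027",
  "city_013",
  "city_024",
  "city_025",
  "city_014",
  "city_011",
  "city_016",
  "city_003",
  "city_004",
  "city_029",
  "city_007",
  "city_006",
  "city_009",
  "city_019",
  "city_002",
  "city_029",
  "city_017",
  "city_011",
  "city_011",
  "city_028",
  "city_012",
  "city_023"
 ],
 "eta": [
  2.54,
  3.63
 ],
 "gamma1": {
  "lat10": 0.06,
  "ln_population": 0.21,
  "loc_NA_Oceania_Japan": -1.25,
  "loc_NW_W_Europe": -1.69,
  "post2005": -0.36,
  "sea_salt_reported": -0.29
 },
 "gamma2": {
  "lat10": 0.13,
  "ln_population": 0.08,
  "loc_NA_Oceania_Japan": -1.11,
  "loc_NW_W_Europe": -1.49,
  "loc_rest_of_Europe": -0.41,
  "sea_salt_reported": -0.33
 },
 "mu1": [
  2.27542476266364,
  2.45355243066206,
  2.0678560930875025,
  2.667138544038412,
  2.6641042292348054,
  2.4033004228581785,
  1.9106528344984774,
  2.1377826152207473,
  2.095463655832817,
  2.0226091557262205,
  2.2117677555535593,
  0.06359493041403619,
  2.8135524306620603,
  2.095463655832817,
  1.013432353041529,
  1.8735404950419294,
  1.0450661207492133,
  2.4554636558328173,
  2.5055566219686156,
  1.7865737237647314,
  1.7326091557262202,
  2.0678560930875025,
  1.013432353041529,
  1.7865737237647314,
  0.8261698551331567,
  1.6167448766523171,
  2.067782615220747,
  2.2006528344984773,
  1.3350661207492132,
  1.8555566219686157,
  0.8071903881365876,
  2.0828772529990416,
  1.8633634156017305,
  0.5658987369138144,
  2.2006528344984773,
  2.45355243066206,
  -0.39341718596447706,
  1.1248278579131248,
  2.9296164651951893,
  3.1981750908678634,
  0.32317006686394034,
  0.706859761962908,
  3.027138544038412,
  1.0548278579131247,
  1.013432353041529,
  0.9258987369138145,
  0.2758987369138146,
  1.4965737237647316,
  0.7904240101932891,
  1.8735404950419294
 ],
 "mu2": [
  3.8841129990626624,
  3.525290102225749,
  3.2768820532169833,
  3.894315642557343,
  4.084519001319228,
  3.7424574181207633,
  3.8605416501015113,
  3.2300986590323135,
  3.3326953523177827,
  4.127933010600564,
  3.6438573323942305,
  1.7506226587903995,
  3.525290102225749,
  3.3326953523177827,
  2.693655997633684,
  3.557295854218384,
  2.71446800349004,
  3.3326953523177827,
  4.1579332187934535,
  3.382391262030828,
  3.797933010600564,
  3.2768820532169833,
  2.693655997633684,
  3.382391262030828,
  2.4342515220716123,
  2.826931043874567,
  3.5600986590323136,
  4.190541650101511,
  3.04446800349004,
  3.8279332187934534,
  2.578214429779802,
  3.798869849201606,
  2.7853386030556084,
  2.4067611854877606,
  4.190541650101511,
  3.525290102225749,
  1.82020930004862,
  2.827475975528197,
  3.942079760560531,
  4.21243228480315,
  2.2415578282811643,
  2.426430083145715,
  3.894315642557343,
  3.157475975528197,
  2.693655997633684,
  2.4067611854877606,
  2.076761185487761,
  3.0523912620308282,
  2.5966877218366644,
  3.557295854218384
 ],
 "n_cities": 30,
 "n_obs": 50,
 "n_share_cap_rejections": 0,
 "regressors": {
  "overall": [
   "ln_population",
   "lat10",
   "sea_salt_reported",
   "loc_NA_Oceania_Japan",
   "loc_NW_W_Europe",
   "loc_rest_of_Europe"
  ],
  "traffic": [
   "ln_population",
   "lat10",
   "sea_salt_reported",
   "post2005",
   "loc_NA_Oceania_Japan",
   "loc_NW_W_Europe"
  ]
 },
 "rho": 0.6,
 "seed": 20220308,
 "sigma": [
  [
   0.25,
   0.105
  ],
  [
   0.105,
   0.12249999999999998
  ]
 ]
}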