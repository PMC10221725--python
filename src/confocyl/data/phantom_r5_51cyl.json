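{
 "version": 1,
 "seed": 7,
 "slab": {
  "y": 200.0,
  "z": 200.0,
  "x": 200.0
 },
 "n_surround": 1.0,
 "achieved_fill": 0.10013826583317466,
 "cylinders": [
  {
   "cy": 23.768138654886727,
   "cz": 75.47062218421934,
   "r": 5.0,
   "n": 1.6285
  },
  {
   "cy": 52.38028114658678,
   "cz": -52.210633901787546,
   "r": 5.0,
   "n": 1.6285
  },
  {
   "cy": -37.968405866867165,
   "cz": 70.97515462528975,
   "r": 5.0,
   "n": 1.6285
  },
  {
   "cy": -93.9995921325408,
   "cz": 61.03339949272561,
   "r": 5.0,
   "n": 1.6285
  },
  {
   "cy": 56.44319146288879,
   "cz": -6.092358959693058,
   "r": 5.0,
   "n": 1.6285
  },
  {
   "cy": -37.42383890433043,
   "cz": -42.099133700853066,
   "r": 5.0,
   "n": 1.6285
  },
  {
   "cy": -46.574778345716325,
   "cz": -10.435501882297146,
   "r": 5.0,
   "n": 1.6285
  },
  {
   "cy": 0.8641692020111265,
   "cz": 10.164496894153572,
   "r": 5.0,
   "n": 1.6285
  },
  {
   "cy": 94.1450538525346,
   "cz": 55.60576465061308,
   "r": 5.0,
   "n": 1.6285
  },
  {
   "cy": 23.214053593820907,
   "cz": 92.90242805955813,
   "r": 5.0,
   "n": 1.6285
  },
  {
   "cy": -54.0913473352362,
   "cz": -64.55971356700954,
   "r": 5.0,
   "n": 1.6285
  },
  {
   "cy": 21.382524811875854,
   "cz": -86.65101848733715,
   "r": 5.0,
   "n": 1.6285
  },
  {
   "cy": -88.22074703301674,
   "cz": 2.8288758515603547,
   "r": 5.0,
   "n": 1.6285
  },
  {
   "cy": -6.420855188195077,
   "cz": 79.26187690664193,
   "r": 5.0,
   "n": 1.6285
  },
  {
   "cy": 24.55298835329198,
   "cz": 2.6823528539076307,
   "r": 5.0,
   "n": 1.6285
  },
  {
   "cy": -0.594047275234189,
   "cz": -47.972164814807144,
   "r": 5.0,
   "n": 1.6285
  },
  {
   "cy": -92.75913514692388,
   "cz": -58.44359264279098,
   "r": 5.0,
   "n": 1.6285
  },
  {
   "cy": 36.48610296754944,
   "cz": -56.88472244247091,
   "r": 5.0,
   "n": 1.6285
  },
  {
   "cy": -24.788100985580726,
   "cz": -94.29049401010558,
   "r": 5.0,
   "n": 1.6285
  },
  {
   "cy": 62.709068662331646,
   "cz": -65.65239459832642,
   "r": 5.0,
   "n": 1.6285
  },
  {
   "cy": 1.86025387500041,
   "cz": 65.95854680951518,
   "r": 5.0,
   "n": 1.6285
  },
  {
   "cy": 26.54626171907998,
   "cz": 45.936479998752844,
   "r": 5.0,
   "n": 1.6285
  },
  {
   "cy": -77.61583503802132,
   "cz": 7.817326061532867,
   "r": 5.0,
   "n": 1.6285
  },
  {
   "cy": -26.359828787310065,
   "cz": 18.654972769370488,
   "r": 5.0,
   "n": 1.6285
  },
  {
   "cy": -83.7421879543543,
   "cz": -21.349957788961547,
   "r": 5.0,
   "n": 1.6285
  },
  {
   "cy": -33.623094210940735,
   "cz": -66.46205147661415,
   "r": 5.0,
   "n": 1.6285
  },
  {
   "cy": 60.10423972562438,
   "cz": -22.905227405440627,
   "r": 5.0,
   "n": 1.6285
  },
  {
   "cy": 90.9620980381321,
   "cz": 17.098421672015945,
   "r": 5.0,
   "n": 1.6285
  },
  {
   "cy": 19.96068822767174,
   "cz": 26.219350349783127,
   "r": 5.0,
   "n": 1.6285
  },
  {
   "cy": -11.340441234244366,
   "cz": -49.48284725239057,
   "r": 5.0,
   "n": 1.6285
  },
  {
   "cy": -18.52532336024349,
   "cz": -76.62622215296832,
   "r": 5.0,
   "n": 1.6285
  },
  {
   "cy": 88.88732969927608,
   "cz": -54.14923290238279,
   "r": 5.0,
   "n": 1.6285
  },
  {
   "cy": 32.63538089614414,
   "cz": -37.92018451897665,
   "r": 5.0,
   "n": 1.6285
  },
  {
   "cy": 71.07463496840583,
   "cz": 30.820800284306216,
   "r": 5.0,
   "n": 1.6285
  },
  {
   "cy": -69.99299499642191,
   "cz": 65.56412096616506,
   "r": 5.0,
   "n": 1.6285
  },
  {
   "cy": 84.54015251754612,
   "cz": 76.74418975722608,
   "r": 5.0,
   "n": 1.6285
  },
  {
   "cy": 13.246638093262675,
   "cz": -67.36260878542389,
   "r": 5.0,
   "n": 1.6285
  },
  {
   "cy": -58.43193595601685,
   "cz": 81.30208010145964,
   "r": 5.0,
   "n": 1.6285
  },
  {
   "cy": 13.24191215002351,
   "cz": -23.505311135315182,
   "r": 5.0,
   "n": 1.6285
  },
  {
   "cy": -87.76911552866457,
   "cz": 71.4815735407615,
   "r": 5.0,
   "n": 1.6285
  },
  {
   "cy": -33.78897114175723,
   "cz": 47.75173477243629,
   "r": 5.0,
   "n": 1.6285
  },
  {
   "cy": -89.2334440670188,
   "cz": -71.65050058104822,
   "r": 5.0,
   "n": 1.6285
  },
  {
   "cy": 88.75816472549985,
   "cz": 29.97453870731775,
   "r": 5.0,
   "n": 1.6285
  },
  {
   "cy": -13.638153185998547,
   "cz": 4.510620502991259,
   "r": 5.0,
   "n": 1.6285
  },
  {
   "cy": 70.83374962730713,
   "cz": -29.599973270755015,
   "r": 5.0,
   "n": 1.6285
  },
  {
   "cy": -27.471382365532705,
   "cz": 3.6287124342381247,
   "r": 5.0,
   "n": 1.6285
  },
  {
   "cy": 50.39700282291929,
   "cz": 77.74406965820452,
   "r": 5.0,
   "n": 1.6285
  },
  {
   "cy": -94.01601549506789,
   "cz": 48.06572568357325,
   "r": 5.0,
   "n": 1.6285
  },
  {
   "cy": -15.408306326494824,
   "cz": 59.89869281905868,
   "r": 5.0,
   "n": 1.6285
  },
  {
   "cy": -92.28847395992399,
   "cz": 24.407770094595236,
   "r": 5.0,
   "n": 1.6285
  },
  {
   "cy": -57.28098188139216,
   "cz": -26.005879395433197,
   "r": 5.0,
   "n": 1.6285
  }
 ]
}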