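# source=allowed-shape beta spectrum, relativistic Fermi function; branch endpoints/intensities from ENSDF (177Lu); generated 2026-09-05
# total_beta_yield=1.0020
energy_MeV,density_per_MeV
0.0010,5.608547e+00
0.0030,5.571431e+00
0.0050,5.534092e+00
0.0070,5.496539e+00
0.0090,5.458778e+00
0.0110,5.420816e+00
0.0130,5.382662e+00
0.0150,5.344321e+00
0.0170,5.305803e+00
0.0190,5.267116e+00
0.0210,5.228268e+00
0.0230,5.189269e+00
0.0250,5.150128e+00
0.0270,5.110854e+00
0.0290,5.071458e+00
0.0310,5.031949e+00
0.0330,4.992336e+00
0.0350,4.952630e+00
0.0370,4.912841e+00
0.0390,4.872977e+00
0.0410,4.833050e+00
0.0430,4.793068e+00
0.0450,4.753041e+00
0.0470,4.712978e+00
0.0490,4.672889e+00
0.0510,4.632784e+00
0.0530,4.592672e+00
0.0550,4.552562e+00
0.0570,4.512463e+00
0.0590,4.472384e+00
0.0610,4.432336e+00
0.0630,4.392327e+00
0.0650,4.352366e+00
0.0670,4.312462e+00
0.0690,4.272625e+00
0.0710,4.232865e+00
0.0730,4.193189e+00
0.0750,4.153609e+00
0.0770,4.114132e+00
0.0790,4.074768e+00
0.0810,4.035527e+00
0.0830,3.996418e+00
0.0850,3.957450e+00
0.0870,3.918634e+00
0.0890,3.879978e+00
0.0910,3.841492e+00
0.0930,3.803186e+00
0.0950,3.765069e+00
0.0970,3.727152e+00
0.0990,3.689444e+00
0.1010,3.651954e+00
0.1030,3.614694e+00
0.1050,3.577673e+00
0.1070,3.540900e+00
0.1090,3.504387e+00
0.1110,3.468143e+00
0.1130,3.432178e+00
0.1150,3.396504e+00
0.1170,3.361129e+00
0.1190,3.326066e+00
0.1210,3.291323e+00
0.1230,3.256913e+00
0.1250,3.222845e+00
0.1270,3.189130e+00
0.1290,3.155779e+00
0.1310,3.122803e+00
0.1330,3.090213e+00
0.1350,3.058020e+00
0.1370,3.026234e+00
0.1390,2.994868e+00
0.1410,2.963932e+00
0.1430,2.933437e+00
0.1450,2.903395e+00
0.1470,2.873817e+00
0.1490,2.844715e+00
0.1510,2.816100e+00
0.1530,2.787984e+00
0.1550,2.760378e+00
0.1570,2.733294e+00
0.1590,2.706745e+00
0.1610,2.680741e+00
0.1630,2.655296e+00
0.1650,2.630420e+00
0.1670,2.606125e+00
0.1690,2.582425e+00
0.1710,2.559331e+00
0.1730,2.536856e+00
0.1750,2.515012e+00
0.1770,2.493810e+00
0.1790,2.472903e+00
0.1810,2.451932e+00
0.1830,2.430902e+00
0.1850,2.409813e+00
0.1870,2.388669e+00
0.1890,2.367470e+00
0.1910,2.346220e+00
0.1930,2.324920e+00
0.1950,2.303573e+00
0.1970,2.282181e+00
0.1990,2.260747e+00
0.2010,2.239272e+00
0.2030,2.217759e+00
0.2050,2.196211e+00
0.2070,2.174629e+00
0.2090,2.153016e+00
0.2110,2.131374e+00
0.2130,2.109707e+00
0.2150,2.088015e+00
0.2170,2.066302e+00
0.2190,2.044570e+00
0.2210,2.022821e+00
0.2230,2.001058e+00
0.2250,1.979284e+00
0.2270,1.957501e+00
0.2290,1.935711e+00
0.2310,1.913918e+00
0.2330,1.892122e+00
0.2350,1.870328e+00
0.2370,1.848538e+00
0.2390,1.826754e+00
0.2410,1.804979e+00
0.2430,1.783216e+00
0.2450,1.761467e+00
0.2470,1.739734e+00
0.2490,1.718021e+00
0.2510,1.696328e+00
0.2530,1.674654e+00
0.2550,1.653002e+00
0.2570,1.631376e+00
0.2590,1.609778e+00
0.2610,1.588210e+00
0.2630,1.566676e+00
0.2650,1.545178e+00
0.2670,1.523718e+00
0.2690,1.502301e+00
0.2710,1.480928e+00
0.2730,1.459601e+00
0.2750,1.438325e+00
0.2770,1.417102e+00
0.2790,1.395935e+00
0.2810,1.374825e+00
0.2830,1.353778e+00
0.2850,1.332794e+00
0.2870,1.311878e+00
0.2890,1.291032e+00
0.2910,1.270258e+00
0.2930,1.249561e+00
0.2950,1.228942e+00
0.2970,1.208406e+00
0.2990,1.187954e+00
0.3010,1.167590e+00
0.3030,1.147316e+00
0.3050,1.127137e+00
0.3070,1.107054e+00
0.3090,1.087072e+00
0.3110,1.067192e+00
0.3130,1.047419e+00
0.3150,1.027754e+00
0.3170,1.008202e+00
0.3190,9.887650e-01
0.3210,9.694466e-01
0.3230,9.502499e-01
0.3250,9.311780e-01
0.3270,9.122340e-01
0.3290,8.934212e-01
0.3310,8.747428e-01
0.3330,8.562020e-01
0.3350,8.378019e-01
0.3370,8.195459e-01
0.3390,8.014372e-01
0.3410,7.834791e-01
0.3430,7.656748e-01
0.3450,7.480276e-01
0.3470,7.305409e-01
0.3490,7.132179e-01
0.3510,6.960620e-01
0.3530,6.790766e-01
0.3550,6.622650e-01
0.3570,6.456305e-01
0.3590,6.291766e-01
0.3610,6.129067e-01
0.3630,5.968241e-01
0.3650,5.809323e-01
0.3670,5.652348e-01
0.3690,5.497349e-01
0.3710,5.344362e-01
0.3730,5.193421e-01
0.3750,5.044562e-01
0.3770,4.897818e-01
0.3790,4.753226e-01
0.3810,4.610820e-01
0.3830,4.470637e-01
0.3850,4.332711e-01
0.3870,4.196818e-01
0.3890,4.062537e-01
0.3910,3.929889e-01
0.3930,3.798900e-01
0.3950,3.669599e-01
0.3970,3.542014e-01
0.3990,3.416173e-01
0.4010,3.292105e-01
0.4030,3.169837e-01
0.4050,3.049399e-01
0.4070,2.930818e-01
0.4090,2.814125e-01
0.4110,2.699347e-01
0.4130,2.586513e-01
0.4150,2.475652e-01
0.4170,2.366794e-01
0.4190,2.259968e-01
0.4210,2.155203e-01
0.4230,2.052528e-01
0.4250,1.951973e-01
0.4270,1.853567e-01
0.4290,1.757341e-01
0.4310,1.663323e-01
0.4330,1.571545e-01
0.4350,1.482035e-01
0.4370,1.394824e-01
0.4390,1.309942e-01
0.4410,1.227420e-01
0.4430,1.147287e-01
0.4450,1.069575e-01
0.4470,9.943135e-02
0.4490,9.215334e-02
0.4510,8.512657e-02
0.4530,7.835410e-02
0.4550,7.183904e-02
0.4570,6.558450e-02
0.4590,5.959359e-02
0.4610,5.386943e-02
0.4630,4.841517e-02
0.4650,4.323393e-02
0.4670,3.832889e-02
0.4690,3.370320e-02
0.4710,2.936003e-02
0.4730,2.530256e-02
0.4750,2.153400e-02
0.4770,1.805754e-02
0.4790,1.487639e-02
0.4810,1.199377e-02
0.4830,9.412913e-03
0.4850,7.137059e-03
0.4870,5.169455e-03
0.4890,3.513361e-03
0.4910,2.172045e-03
0.4930,1.148783e-03
0.4950,4.468634e-04
0.4970,6.958109e-05
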