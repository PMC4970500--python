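# Na  Z=11  E(eV) f1 f2  (Cromer-Liberman, f1 = Z + f')
1.000000e+02	5.695110e+00	6.317872e+00
1.036524e+02	5.944885e+00	6.274828e+00
1.074382e+02	6.347722e+00	6.219524e+00
1.113623e+02	6.589100e+00	6.131154e+00
1.154297e+02	6.822739e+00	6.035297e+00
1.196456e+02	7.048477e+00	5.932386e+00
1.240156e+02	7.266084e+00	5.822879e+00
1.285451e+02	8.395032e+00	5.624489e+00
1.332401e+02	8.543673e+00	5.422498e+00
1.381066e+02	8.680170e+00	5.225225e+00
1.431508e+02	8.805420e+00	5.032708e+00
1.483792e+02	8.920237e+00	4.844972e+00
1.537987e+02	9.025359e+00	4.662033e+00
1.594160e+02	9.121458e+00	4.483894e+00
1.652385e+02	9.209152e+00	4.310552e+00
1.712737e+02	9.289008e+00	4.141993e+00
1.775293e+02	9.361551e+00	3.978195e+00
1.840134e+02	9.427265e+00	3.819128e+00
1.907343e+02	9.486599e+00	3.664754e+00
1.977007e+02	9.539970e+00	3.515030e+00
2.049215e+02	9.587766e+00	3.369905e+00
2.124061e+02	9.630348e+00	3.229323e+00
2.201640e+02	9.668052e+00	3.093222e+00
2.282053e+02	9.701189e+00	2.961537e+00
2.365403e+02	9.730053e+00	2.834196e+00
2.451797e+02	9.754913e+00	2.711125e+00
2.541346e+02	9.823680e+00	2.591763e+00
2.634167e+02	9.839376e+00	2.472513e+00
2.730377e+02	9.851505e+00	2.357705e+00
2.830101e+02	9.860307e+00	2.247244e+00
2.933468e+02	9.866011e+00	2.141034e+00
3.040610e+02	9.868824e+00	2.038973e+00
3.151666e+02	9.868936e+00	1.940959e+00
3.266777e+02	9.866519e+00	1.846889e+00
3.386093e+02	9.861729e+00	1.756657e+00
3.509767e+02	9.854703e+00	1.670156e+00
3.637958e+02	9.845562e+00	1.587278e+00
3.770831e+02	9.834410e+00	1.507918e+00
3.908557e+02	9.821334e+00	1.431966e+00
4.051313e+02	9.806404e+00	1.359315e+00
4.199283e+02	9.789671e+00	1.289860e+00
4.352658e+02	9.771165e+00	1.223493e+00
4.511635e+02	9.750899e+00	1.160110e+00
4.676418e+02	9.728861e+00	1.099606e+00
4.847219e+02	9.705016e+00	1.041879e+00
5.024259e+02	9.679301e+00	9.868286e-01
5.207766e+02	9.651621e+00	9.343547e-01
5.397974e+02	9.621846e+00	8.843600e-01
5.595130e+02	9.589802e+00	8.367490e-01
5.799487e+02	9.555263e+00	7.914282e-01
6.011308e+02	9.531272e+00	7.477256e-01
6.230865e+02	9.489017e+00	7.061719e-01
6.458441e+02	9.443317e+00	6.668107e-01
6.694330e+02	9.393575e+00	6.295302e-01
6.938833e+02	9.339028e+00	5.942238e-01
7.192268e+02	9.278681e+00	5.607906e-01
7.454958e+02	9.211227e+00	5.291343e-01
7.727244e+02	9.134904e+00	4.991640e-01
8.009474e+02	9.047283e+00	4.707930e-01
8.302012e+02	8.944898e+00	4.439390e-01
8.605235e+02	8.822603e+00	4.185241e-01
8.919533e+02	8.672327e+00	3.944743e-01
9.245310e+02	8.480466e+00	3.717191e-01
9.582986e+02	8.221600e+00	3.501919e-01
9.932996e+02	7.840026e+00	3.298294e-01
1.029579e+03	7.172107e+00	3.103789e-01
1.067183e+03	4.883493e+00	2.919990e-01
1.106161e+03	6.512966e+00	3.871975e+00
1.146563e+03	8.476613e+00	4.033534e+00
1.188440e+03	9.136259e+00	3.800856e+00
1.231846e+03	9.593106e+00	3.581934e+00
1.276838e+03	9.930954e+00	3.376121e+00
1.323474e+03	1.019381e+01	3.182606e+00
1.371812e+03	1.040376e+01	3.000627e+00
1.421916e+03	1.054803e+01	2.834756e+00
1.473850e+03	1.069307e+01	2.681193e+00
1.527681e+03	1.081506e+01	2.534848e+00
1.583479e+03	1.091804e+01	2.395450e+00
1.641314e+03	1.100514e+01	2.262732e+00
1.701261e+03	1.107881e+01	2.136435e+00
1.763398e+03	1.114101e+01	2.016307e+00
1.827804e+03	1.119336e+01	1.902101e+00
1.894563e+03	1.123719e+01	1.793579e+00
1.963760e+03	1.127363e+01	1.690507e+00
2.035485e+03	1.130363e+01	1.592659e+00
2.109829e+03	1.132801e+01	1.499815e+00
2.186888e+03	1.135066e+01	1.411415e+00
2.266762e+03	1.136526e+01	1.327479e+00
2.349554e+03	1.137608e+01	1.248110e+00
2.435369e+03	1.138363e+01	1.173087e+00
2.524318e+03	1.138833e+01	1.102199e+00
2.616517e+03	1.139056e+01	1.035242e+00
2.712082e+03	1.139066e+01	9.720202e-01
2.811139e+03	1.138891e+01	9.123484e-01
2.913813e+03	1.138558e+01	8.560472e-01
3.020237e+03	1.138089e+01	8.028666e-01
3.130548e+03	1.137498e+01	7.524453e-01
3.244888e+03	1.136804e+01	7.050044e-01
3.363405e+03	1.136024e+01	6.603799e-01
3.486250e+03	1.135174e+01	6.184164e-01
3.613582e+03	1.134269e+01	5.789661e-01
3.745564e+03	1.133319e+01	5.418888e-01
3.882368e+03	1.132337e+01	5.070513e-01
4.024167e+03	1.131330e+01	4.743274e-01
4.171146e+03	1.130307e+01	4.435976e-01
4.323493e+03	1.129275e+01	4.147482e-01
4.481405e+03	1.128239e+01	3.876718e-01
4.645084e+03	1.127221e+01	3.622665e-01
4.814741e+03	1.126326e+01	3.382755e-01
4.990595e+03	1.125289e+01	3.158058e-01
5.172871e+03	1.124268e+01	2.947663e-01
5.361806e+03	1.123263e+01	2.750702e-01
5.557640e+03	1.122278e+01	2.566359e-01
5.760628e+03	1.121314e+01	2.393861e-01
5.971029e+03	1.120374e+01	2.232484e-01
6.189115e+03	1.119458e+01	2.081544e-01
6.415167e+03	1.118568e+01	1.940397e-01
6.649475e+03	1.117704e+01	1.808436e-01
6.892340e+03	1.116867e+01	1.685090e-01
7.144076e+03	1.116058e+01	1.569823e-01
7.405007e+03	1.115276e+01	1.462129e-01
7.675468e+03	1.114521e+01	1.361533e-01
7.955807e+03	1.113793e+01	1.267587e-01
8.246385e+03	1.113093e+01	1.179871e-01
8.547576e+03	1.112419e+01	1.097991e-01
8.859768e+03	1.111772e+01	1.021574e-01
9.183363e+03	1.111149e+01	9.496334e-02
9.518776e+03	1.110551e+01	8.825328e-02
9.866441e+03	1.109977e+01	8.200463e-02
1.022680e+04	1.109427e+01	7.618656e-02
1.060033e+04	1.108900e+01	7.077028e-02
1.098749e+04	1.108397e+01	6.572882e-02
1.138880e+04	1.107916e+01	6.103700e-02
1.180477e+04	1.107457e+01	5.667126e-02
1.223592e+04	1.107019e+01	5.260958e-02
1.268283e+04	1.106601e+01	4.883138e-02
1.314606e+04	1.106203e+01	4.531745e-02
1.362620e+04	1.105824e+01	4.204981e-02
1.412389e+04	1.105463e+01	3.901169e-02
1.463975e+04	1.105120e+01	3.618739e-02
1.517445e+04	1.104794e+01	3.356232e-02
1.572869e+04	1.104484e+01	3.112280e-02
1.630316e+04	1.104190e+01	2.885609e-02
1.689862e+04	1.103910e+01	2.675028e-02
1.751582e+04	1.103645e+01	2.479426e-02
1.815557e+04	1.103393e+01	2.297767e-02
1.881869e+04	1.103155e+01	2.129083e-02
1.950602e+04	1.102929e+01	1.972474e-02
2.021846e+04	1.102714e+01	1.827098e-02
2.095692e+04	1.102512e+01	1.692172e-02
2.172235e+04	1.102320e+01	1.566963e-02
2.251574e+04	1.102138e+01	1.450792e-02
2.333811e+04	1.101968e+01	1.342965e-02
2.419051e+04	1.101805e+01	1.242957e-02
2.507404e+04	1.101651e+01	1.150261e-02
2.598985e+04	1.101505e+01	1.064353e-02
2.693910e+04	1.101368e+01	9.847469e-03
2.792303e+04	1.101238e+01	9.109876e-03
2.894289e+04	1.101116e+01	8.426465e-03
3.000000e+04	1.101000e+01	7.793337e-03
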