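# P  Z=15  E(eV) f1 f2  (Cromer-Liberman, f1 = Z + f')
1.000000e+02	2.395798e+00	5.757966e-01
1.036524e+02	2.100722e+00	5.734441e-01
1.074382e+02	1.740836e+00	5.705259e-01
1.113623e+02	1.292755e+00	5.670462e-01
1.154297e+02	7.193200e-01	5.630116e-01
1.196456e+02	4.781574e-03	5.580369e-01
1.240156e+02	-9.733339e-01	5.457354e-01
1.285451e+02	-2.606467e+00	5.331400e-01
1.332401e+02	-7.802028e+00	1.076432e+01
1.381066e+02	-1.995619e+00	1.075653e+01
1.431508e+02	1.759851e-01	1.072844e+01
1.483792e+02	1.612153e+00	1.068013e+01
1.537987e+02	2.716323e+00	1.061185e+01
1.594160e+02	3.625077e+00	1.052394e+01
1.652385e+02	4.398215e+00	1.041684e+01
1.712737e+02	5.062931e+00	1.029114e+01
1.775293e+02	5.626198e+00	1.014750e+01
1.840134e+02	6.072513e+00	9.986684e+00
1.907343e+02	6.063327e+00	1.093003e+01
1.977007e+02	7.244338e+00	1.075093e+01
2.049215e+02	7.987393e+00	1.055609e+01
2.124061e+02	8.619582e+00	1.034657e+01
2.201640e+02	9.187343e+00	1.012345e+01
2.282053e+02	1.035523e+01	9.819034e+00
2.365403e+02	1.078404e+01	9.469925e+00
2.451797e+02	1.116907e+01	9.127659e+00
2.541346e+02	1.151639e+01	8.792401e+00
2.634167e+02	1.183062e+01	8.464291e+00
2.730377e+02	1.211629e+01	8.143444e+00
2.830101e+02	1.237470e+01	7.829933e+00
2.933468e+02	1.260930e+01	7.523881e+00
3.040610e+02	1.282222e+01	7.225351e+00
3.151666e+02	1.301534e+01	6.934391e+00
3.266777e+02	1.323670e+01	6.646169e+00
3.386093e+02	1.339230e+01	6.362799e+00
3.509767e+02	1.353167e+01	6.087941e+00
3.637958e+02	1.365613e+01	5.821572e+00
3.770831e+02	1.376689e+01	5.563654e+00
3.908557e+02	1.386504e+01	5.314133e+00
4.051313e+02	1.395158e+01	5.072938e+00
4.199283e+02	1.402742e+01	4.839983e+00
4.352658e+02	1.409338e+01	4.615172e+00
4.511635e+02	1.415025e+01	4.398393e+00
4.676418e+02	1.419872e+01	4.189525e+00
4.847219e+02	1.423947e+01	3.988436e+00
5.024259e+02	1.427309e+01	3.794985e+00
5.207766e+02	1.430016e+01	3.609023e+00
5.397974e+02	1.437141e+01	3.427546e+00
5.595130e+02	1.438117e+01	3.252024e+00
5.799487e+02	1.438603e+01	3.084519e+00
6.011308e+02	1.438647e+01	2.924723e+00
6.230865e+02	1.438292e+01	2.772338e+00
6.458441e+02	1.437576e+01	2.627071e+00
6.694330e+02	1.436532e+01	2.488638e+00
6.938833e+02	1.435191e+01	2.356764e+00
7.192268e+02	1.433579e+01	2.231180e+00
7.454958e+02	1.431720e+01	2.111629e+00
7.727244e+02	1.430055e+01	1.997622e+00
8.009474e+02	1.427688e+01	1.889080e+00
8.302012e+02	1.425126e+01	1.785968e+00
8.605235e+02	1.422381e+01	1.688047e+00
8.919533e+02	1.419464e+01	1.595087e+00
9.245310e+02	1.416381e+01	1.506864e+00
9.582986e+02	1.413134e+01	1.423163e+00
9.932996e+02	1.409724e+01	1.343777e+00
1.029579e+03	1.406175e+01	1.267722e+00
1.067183e+03	1.402438e+01	1.195571e+00
1.106161e+03	1.398499e+01	1.127318e+00
1.146563e+03	1.394348e+01	1.062767e+00
1.188440e+03	1.389966e+01	1.001730e+00
1.231846e+03	1.385326e+01	9.440259e-01
1.276838e+03	1.380394e+01	8.894850e-01
1.323474e+03	1.375122e+01	8.379437e-01
1.371812e+03	1.369448e+01	7.892464e-01
1.421916e+03	1.363291e+01	7.432448e-01
1.473850e+03	1.356543e+01	6.997980e-01
1.527681e+03	1.349061e+01	6.587714e-01
1.583479e+03	1.340645e+01	6.200372e-01
1.641314e+03	1.331017e+01	5.834740e-01
1.701261e+03	1.319765e+01	5.489660e-01
1.763398e+03	1.306259e+01	5.164034e-01
1.827804e+03	1.289458e+01	4.856818e-01
1.894563e+03	1.267482e+01	4.567020e-01
1.963760e+03	1.236415e+01	4.293700e-01
2.035485e+03	1.185793e+01	4.035965e-01
2.109829e+03	1.064101e+01	3.792965e-01
2.186888e+03	1.101719e+01	4.031983e+00
2.266762e+03	1.249161e+01	3.856579e+00
2.349554e+03	1.319275e+01	3.642229e+00
2.435369e+03	1.365498e+01	3.439653e+00
2.524318e+03	1.399363e+01	3.248199e+00
2.616517e+03	1.425428e+01	3.067270e+00
2.712082e+03	1.446162e+01	2.896312e+00
2.811139e+03	1.462741e+01	2.734978e+00
2.913813e+03	1.476739e+01	2.582626e+00
3.020237e+03	1.488391e+01	2.437664e+00
3.130548e+03	1.498135e+01	2.299520e+00
3.244888e+03	1.506250e+01	2.168429e+00
3.363405e+03	1.513015e+01	2.044079e+00
3.486250e+03	1.518646e+01	1.926166e+00
3.613582e+03	1.523500e+01	1.814356e+00
3.745564e+03	1.527328e+01	1.708371e+00
3.882368e+03	1.530449e+01	1.608001e+00
4.024167e+03	1.532961e+01	1.512985e+00
4.171146e+03	1.534944e+01	1.423072e+00
4.323493e+03	1.536975e+01	1.337809e+00
4.481405e+03	1.538051e+01	1.256517e+00
4.645084e+03	1.538778e+01	1.179824e+00
4.814741e+03	1.539203e+01	1.107493e+00
4.990595e+03	1.539370e+01	1.039295e+00
5.172871e+03	1.539316e+01	9.750143e-01
5.361806e+03	1.539071e+01	9.144440e-01
5.557640e+03	1.538665e+01	8.573872e-01
5.760628e+03	1.538122e+01	8.036565e-01
5.971029e+03	1.537464e+01	7.530734e-01
6.189115e+03	1.536708e+01	7.054681e-01
6.415167e+03	1.535873e+01	6.606789e-01
6.649475e+03	1.534980e+01	6.185517e-01
6.892340e+03	1.534026e+01	5.789401e-01
7.144076e+03	1.533032e+01	5.417065e-01
7.405007e+03	1.532006e+01	5.067189e-01
7.675468e+03	1.530959e+01	4.738518e-01
7.955807e+03	1.529897e+01	4.429864e-01
8.246385e+03	1.528827e+01	4.140095e-01
8.547576e+03	1.527755e+01	3.868141e-01
8.859768e+03	1.526687e+01	3.612985e-01
9.183363e+03	1.525619e+01	3.373269e-01
9.518776e+03	1.524763e+01	3.147263e-01
9.866441e+03	1.523701e+01	2.935167e-01
1.022680e+04	1.522657e+01	2.736888e-01
1.060033e+04	1.521635e+01	2.551558e-01
1.098749e+04	1.520637e+01	2.378361e-01
1.138880e+04	1.519663e+01	2.216532e-01
1.180477e+04	1.518717e+01	2.065352e-01
1.223592e+04	1.517798e+01	1.924144e-01
1.268283e+04	1.516907e+01	1.792275e-01
1.314606e+04	1.516045e+01	1.669150e-01
1.362620e+04	1.515213e+01	1.554208e-01
1.412389e+04	1.514410e+01	1.446925e-01
1.463975e+04	1.513635e+01	1.346808e-01
1.517445e+04	1.512890e+01	1.253397e-01
1.572869e+04	1.512174e+01	1.166257e-01
1.630316e+04	1.511486e+01	1.084982e-01
1.689862e+04	1.510826e+01	1.009192e-01
1.751582e+04	1.510193e+01	9.385278e-02
1.815557e+04	1.509586e+01	8.726560e-02
1.881869e+04	1.509006e+01	8.112625e-02
1.950602e+04	1.508451e+01	7.540531e-02
2.021846e+04	1.507920e+01	7.007525e-02
2.095692e+04	1.507413e+01	6.511027e-02
2.172235e+04	1.506930e+01	6.048620e-02
2.251574e+04	1.506468e+01	5.618044e-02
2.333811e+04	1.506028e+01	5.217179e-02
2.419051e+04	1.505609e+01	4.844046e-02
2.507404e+04	1.505210e+01	4.496788e-02
2.598985e+04	1.504830e+01	4.173672e-02
2.693910e+04	1.504468e+01	3.872512e-02
2.792303e+04	1.504122e+01	3.590985e-02
2.894289e+04	1.503794e+01	3.329512e-02
3.000000e+04	1.503482e+01	3.086694e-02
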