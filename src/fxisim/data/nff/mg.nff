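# Mg  Z=12  E(eV) f1 f2  (Cromer-Liberman, f1 = Z + f')
1.000000e+02	5.112198e+00	8.056551e+00
1.036524e+02	5.504877e+00	7.935397e+00
1.074382e+02	5.870279e+00	7.808861e+00
1.113623e+02	6.213567e+00	7.677241e+00
1.154297e+02	6.537847e+00	7.540841e+00
1.196456e+02	6.845193e+00	7.399968e+00
1.240156e+02	7.137093e+00	7.254934e+00
1.285451e+02	7.414663e+00	7.106053e+00
1.332401e+02	7.678777e+00	6.953640e+00
1.381066e+02	7.930136e+00	6.798011e+00
1.431508e+02	8.169314e+00	6.639484e+00
1.483792e+02	8.396797e+00	6.478376e+00
1.537987e+02	8.691318e+00	6.308010e+00
1.594160e+02	8.893463e+00	6.129398e+00
1.652385e+02	9.083359e+00	5.950280e+00
1.712737e+02	9.261524e+00	5.771034e+00
1.775293e+02	9.428432e+00	5.592026e+00
1.840134e+02	9.584522e+00	5.413605e+00
1.907343e+02	9.730210e+00	5.236107e+00
1.977007e+02	9.865893e+00	5.059853e+00
2.049215e+02	9.991977e+00	4.885147e+00
2.124061e+02	1.047506e+01	4.679513e+00
2.201640e+02	1.055753e+01	4.477432e+00
2.282053e+02	1.063077e+01	4.282338e+00
2.365403e+02	1.069555e+01	4.094094e+00
2.451797e+02	1.075255e+01	3.912556e+00
2.541346e+02	1.080240e+01	3.737580e+00
2.634167e+02	1.084569e+01	3.569015e+00
2.730377e+02	1.088294e+01	3.406710e+00
2.830101e+02	1.091461e+01	3.250511e+00
2.933468e+02	1.094116e+01	3.100262e+00
3.040610e+02	1.096298e+01	2.955808e+00
3.151666e+02	1.098044e+01	2.816990e+00
3.266777e+02	1.099388e+01	2.683652e+00
3.386093e+02	1.100360e+01	2.555636e+00
3.509767e+02	1.100988e+01	2.432787e+00
3.637958e+02	1.103921e+01	2.313707e+00
3.770831e+02	1.103788e+01	2.198360e+00
3.908557e+02	1.103370e+01	2.088011e+00
4.051313e+02	1.102687e+01	1.982496e+00
4.199283e+02	1.101761e+01	1.881653e+00
4.352658e+02	1.100608e+01	1.785320e+00
4.511635e+02	1.099242e+01	1.693340e+00
4.676418e+02	1.097677e+01	1.605556e+00
4.847219e+02	1.095923e+01	1.521816e+00
5.024259e+02	1.093989e+01	1.441967e+00
5.207766e+02	1.091882e+01	1.365863e+00
5.397974e+02	1.089604e+01	1.293360e+00
5.595130e+02	1.087158e+01	1.224315e+00
5.799487e+02	1.084542e+01	1.158592e+00
6.011308e+02	1.081754e+01	1.096055e+00
6.230865e+02	1.078787e+01	1.036574e+00
6.458441e+02	1.075630e+01	9.800212e-01
6.694330e+02	1.072269e+01	9.262736e-01
6.938833e+02	1.068686e+01	8.752109e-01
7.192268e+02	1.064856e+01	8.267170e-01
7.454958e+02	1.060748e+01	7.806792e-01
7.727244e+02	1.056322e+01	7.369886e-01
8.009474e+02	1.051527e+01	6.955401e-01
8.302012e+02	1.046299e+01	6.562321e-01
8.605235e+02	1.040551e+01	6.189665e-01
8.919533e+02	1.034175e+01	5.836489e-01
9.245310e+02	1.027023e+01	5.501884e-01
9.582986e+02	1.018894e+01	5.184975e-01
9.932996e+02	1.009512e+01	4.884891e-01
1.029579e+03	9.986386e+00	4.597255e-01
1.067183e+03	9.852982e+00	4.325258e-01
1.106161e+03	9.685830e+00	4.068960e-01
1.146563e+03	9.467196e+00	3.827461e-01
1.188440e+03	9.160438e+00	3.599911e-01
1.231846e+03	8.672508e+00	3.385509e-01
1.276838e+03	7.613879e+00	3.183503e-01
1.323474e+03	7.169637e+00	3.999728e+00
1.371812e+03	9.119119e+00	4.048170e+00
1.421916e+03	9.924381e+00	3.821282e+00
1.473850e+03	1.044368e+01	3.606895e+00
1.527681e+03	1.081998e+01	3.404331e+00
1.583479e+03	1.110862e+01	3.212949e+00
1.641314e+03	1.133743e+01	3.032142e+00
1.701261e+03	1.150669e+01	2.861802e+00
1.763398e+03	1.166098e+01	2.705935e+00
1.827804e+03	1.179003e+01	2.557438e+00
1.894563e+03	1.189850e+01	2.416029e+00
1.963760e+03	1.198991e+01	2.281437e+00
2.035485e+03	1.206699e+01	2.153395e+00
2.109829e+03	1.213191e+01	2.031643e+00
2.186888e+03	1.218643e+01	1.915929e+00
2.266762e+03	1.223200e+01	1.806007e+00
2.349554e+03	1.226981e+01	1.701638e+00
2.435369e+03	1.230090e+01	1.602590e+00
2.524318e+03	1.232613e+01	1.508638e+00
2.616517e+03	1.234760e+01	1.419544e+00
2.712082e+03	1.236285e+01	1.334951e+00
2.811139e+03	1.237418e+01	1.254966e+00
2.913813e+03	1.238215e+01	1.179368e+00
3.020237e+03	1.238734e+01	1.107800e+00
3.130548e+03	1.239029e+01	1.039688e+00
3.244888e+03	1.239070e+01	9.754986e-01
3.363405e+03	1.238903e+01	9.150226e-01
3.486250e+03	1.238563e+01	8.580616e-01
3.613582e+03	1.238078e+01	8.044266e-01
3.745564e+03	1.237472e+01	7.539377e-01
3.882368e+03	1.236765e+01	7.064240e-01
4.024167e+03	1.235974e+01	6.617231e-01
4.171146e+03	1.235116e+01	6.196804e-01
4.323493e+03	1.234203e+01	5.801493e-01
4.481405e+03	1.233248e+01	5.429904e-01
4.645084e+03	1.232259e+01	5.080715e-01
4.814741e+03	1.231247e+01	4.752669e-01
4.990595e+03	1.230219e+01	4.444575e-01
5.172871e+03	1.229181e+01	4.155305e-01
5.361806e+03	1.228140e+01	3.883786e-01
5.557640e+03	1.227101e+01	3.629003e-01
5.760628e+03	1.226191e+01	3.389309e-01
5.971029e+03	1.225151e+01	3.164123e-01
6.189115e+03	1.224125e+01	2.953268e-01
6.415167e+03	1.223117e+01	2.755876e-01
6.649475e+03	1.222128e+01	2.571127e-01
6.892340e+03	1.221161e+01	2.398251e-01
7.144076e+03	1.220218e+01	2.236520e-01
7.405007e+03	1.219299e+01	2.085248e-01
7.675468e+03	1.218407e+01	1.943791e-01
7.955807e+03	1.217540e+01	1.811541e-01
8.246385e+03	1.216701e+01	1.687926e-01
8.547576e+03	1.215889e+01	1.572407e-01
8.859768e+03	1.215104e+01	1.464480e-01
9.183363e+03	1.214350e+01	1.362648e-01
9.518776e+03	1.213621e+01	1.267555e-01
9.866441e+03	1.212917e+01	1.178912e-01
1.022680e+04	1.212240e+01	1.096295e-01
1.060033e+04	1.211588e+01	1.019306e-01
1.098749e+04	1.210962e+01	9.475733e-02
1.138880e+04	1.210361e+01	8.807492e-02
1.180477e+04	1.209786e+01	8.185075e-02
1.223592e+04	1.209234e+01	7.605434e-02
1.268283e+04	1.208707e+01	7.065716e-02
1.314606e+04	1.208203e+01	6.563252e-02
1.362620e+04	1.207721e+01	6.095547e-02
1.412389e+04	1.207261e+01	5.660267e-02
1.463975e+04	1.206823e+01	5.255230e-02
1.517445e+04	1.206405e+01	4.878396e-02
1.572869e+04	1.206006e+01	4.527858e-02
1.630316e+04	1.205627e+01	4.201834e-02
1.689862e+04	1.205266e+01	3.898659e-02
1.751582e+04	1.204923e+01	3.616779e-02
1.815557e+04	1.204597e+01	3.354740e-02
1.881869e+04	1.204287e+01	3.111186e-02
1.950602e+04	1.203992e+01	2.884850e-02
2.021846e+04	1.203713e+01	2.674548e-02
2.095692e+04	1.203448e+01	2.479178e-02
2.172235e+04	1.203196e+01	2.297709e-02
2.251574e+04	1.202958e+01	2.129179e-02
2.333811e+04	1.202732e+01	1.972693e-02
2.419051e+04	1.202517e+01	1.827412e-02
2.507404e+04	1.202315e+01	1.692557e-02
2.598985e+04	1.202123e+01	1.567400e-02
2.693910e+04	1.201941e+01	1.451258e-02
2.792303e+04	1.201769e+01	1.343511e-02
2.894289e+04	1.201606e+01	1.243599e-02
3.000000e+04	1.201452e+01	1.150963e-02
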