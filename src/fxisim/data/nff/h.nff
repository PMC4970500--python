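# H  Z=1  E(eV) f1 f2  (Cromer-Liberman, f1 = Z + f')
1.000000e+02	1.000000e+00	0.000000e+00
1.036524e+02	1.000000e+00	0.000000e+00
1.074382e+02	1.000000e+00	0.000000e+00
1.113623e+02	1.000000e+00	0.000000e+00
1.154297e+02	1.000000e+00	0.000000e+00
1.196456e+02	1.000000e+00	0.000000e+00
1.240156e+02	1.000000e+00	0.000000e+00
1.285451e+02	1.000000e+00	0.000000e+00
1.332401e+02	1.000000e+00	0.000000e+00
1.381066e+02	1.000000e+00	0.000000e+00
1.431508e+02	1.000000e+00	0.000000e+00
1.483792e+02	1.000000e+00	0.000000e+00
1.537987e+02	1.000000e+00	0.000000e+00
1.594160e+02	1.000000e+00	0.000000e+00
1.652385e+02	1.000000e+00	0.000000e+00
1.712737e+02	1.000000e+00	0.000000e+00
1.775293e+02	1.000000e+00	0.000000e+00
1.840134e+02	1.000000e+00	0.000000e+00
1.907343e+02	1.000000e+00	0.000000e+00
1.977007e+02	1.000000e+00	0.000000e+00
2.049215e+02	1.000000e+00	0.000000e+00
2.124061e+02	1.000000e+00	0.000000e+00
2.201640e+02	1.000000e+00	0.000000e+00
2.282053e+02	1.000000e+00	0.000000e+00
2.365403e+02	1.000000e+00	0.000000e+00
2.451797e+02	1.000000e+00	0.000000e+00
2.541346e+02	1.000000e+00	0.000000e+00
2.634167e+02	1.000000e+00	0.000000e+00
2.730377e+02	1.000000e+00	0.000000e+00
2.830101e+02	1.000000e+00	0.000000e+00
2.933468e+02	1.000000e+00	0.000000e+00
3.040610e+02	1.000000e+00	0.000000e+00
3.151666e+02	1.000000e+00	0.000000e+00
3.266777e+02	1.000000e+00	0.000000e+00
3.386093e+02	1.000000e+00	0.000000e+00
3.509767e+02	1.000000e+00	0.000000e+00
3.637958e+02	1.000000e+00	0.000000e+00
3.770831e+02	1.000000e+00	0.000000e+00
3.908557e+02	1.000000e+00	0.000000e+00
4.051313e+02	1.000000e+00	0.000000e+00
4.199283e+02	1.000000e+00	0.000000e+00
4.352658e+02	1.000000e+00	0.000000e+00
4.511635e+02	1.000000e+00	0.000000e+00
4.676418e+02	1.000000e+00	0.000000e+00
4.847219e+02	1.000000e+00	0.000000e+00
5.024259e+02	1.000000e+00	0.000000e+00
5.207766e+02	1.000000e+00	0.000000e+00
5.397974e+02	1.000000e+00	0.000000e+00
5.595130e+02	1.000000e+00	0.000000e+00
5.799487e+02	1.000000e+00	0.000000e+00
6.011308e+02	1.000000e+00	0.000000e+00
6.230865e+02	1.000000e+00	0.000000e+00
6.458441e+02	1.000000e+00	0.000000e+00
6.694330e+02	1.000000e+00	0.000000e+00
6.938833e+02	1.000000e+00	0.000000e+00
7.192268e+02	1.000000e+00	0.000000e+00
7.454958e+02	1.000000e+00	0.000000e+00
7.727244e+02	1.000000e+00	0.000000e+00
8.009474e+02	1.000000e+00	0.000000e+00
8.302012e+02	1.000000e+00	0.000000e+00
8.605235e+02	1.000000e+00	0.000000e+00
8.919533e+02	1.000000e+00	0.000000e+00
9.245310e+02	1.000000e+00	0.000000e+00
9.582986e+02	1.000000e+00	0.000000e+00
9.932996e+02	1.000000e+00	0.000000e+00
1.029579e+03	1.000000e+00	0.000000e+00
1.067183e+03	1.000000e+00	0.000000e+00
1.106161e+03	1.000000e+00	0.000000e+00
1.146563e+03	1.000000e+00	0.000000e+00
1.188440e+03	1.000000e+00	0.000000e+00
1.231846e+03	1.000000e+00	0.000000e+00
1.276838e+03	1.000000e+00	0.000000e+00
1.323474e+03	1.000000e+00	0.000000e+00
1.371812e+03	1.000000e+00	0.000000e+00
1.421916e+03	1.000000e+00	0.000000e+00
1.473850e+03	1.000000e+00	0.000000e+00
1.527681e+03	1.000000e+00	0.000000e+00
1.583479e+03	1.000000e+00	0.000000e+00
1.641314e+03	1.000000e+00	0.000000e+00
1.701261e+03	1.000000e+00	0.000000e+00
1.763398e+03	1.000000e+00	0.000000e+00
1.827804e+03	1.000000e+00	0.000000e+00
1.894563e+03	1.000000e+00	0.000000e+00
1.963760e+03	1.000000e+00	0.000000e+00
2.035485e+03	1.000000e+00	0.000000e+00
2.109829e+03	1.000000e+00	0.000000e+00
2.186888e+03	1.000000e+00	0.000000e+00
2.266762e+03	1.000000e+00	0.000000e+00
2.349554e+03	1.000000e+00	0.000000e+00
2.435369e+03	1.000000e+00	0.000000e+00
2.524318e+03	1.000000e+00	0.000000e+00
2.616517e+03	1.000000e+00	0.000000e+00
2.712082e+03	1.000000e+00	0.000000e+00
2.811139e+03	1.000000e+00	0.000000e+00
2.913813e+03	1.000000e+00	0.000000e+00
3.020237e+03	1.000000e+00	0.000000e+00
3.130548e+03	1.000000e+00	0.000000e+00
3.244888e+03	1.000000e+00	0.000000e+00
3.363405e+03	1.000000e+00	0.000000e+00
3.486250e+03	1.000000e+00	0.000000e+00
3.613582e+03	1.000000e+00	0.000000e+00
3.745564e+03	1.000000e+00	0.000000e+00
3.882368e+03	1.000000e+00	0.000000e+00
4.024167e+03	1.000000e+00	0.000000e+00
4.171146e+03	1.000000e+00	0.000000e+00
4.323493e+03	1.000000e+00	0.000000e+00
4.481405e+03	1.000000e+00	0.000000e+00
4.645084e+03	1.000000e+00	0.000000e+00
4.814741e+03	1.000000e+00	0.000000e+00
4.990595e+03	1.000000e+00	0.000000e+00
5.172871e+03	1.000000e+00	0.000000e+00
5.361806e+03	1.000000e+00	0.000000e+00
5.557640e+03	1.000000e+00	0.000000e+00
5.760628e+03	1.000000e+00	0.000000e+00
5.971029e+03	1.000000e+00	0.000000e+00
6.189115e+03	1.000000e+00	0.000000e+00
6.415167e+03	1.000000e+00	0.000000e+00
6.649475e+03	1.000000e+00	0.000000e+00
6.892340e+03	1.000000e+00	0.000000e+00
7.144076e+03	1.000000e+00	0.000000e+00
7.405007e+03	1.000000e+00	0.000000e+00
7.675468e+03	1.000000e+00	0.000000e+00
7.955807e+03	1.000000e+00	0.000000e+00
8.246385e+03	1.000000e+00	0.000000e+00
8.547576e+03	1.000000e+00	0.000000e+00
8.859768e+03	1.000000e+00	0.000000e+00
9.183363e+03	1.000000e+00	0.000000e+00
9.518776e+03	1.000000e+00	0.000000e+00
9.866441e+03	1.000000e+00	0.000000e+00
1.022680e+04	1.000000e+00	0.000000e+00
1.060033e+04	1.000000e+00	0.000000e+00
1.098749e+04	1.000000e+00	0.000000e+00
1.138880e+04	1.000000e+00	0.000000e+00
1.180477e+04	1.000000e+00	0.000000e+00
1.223592e+04	1.000000e+00	0.000000e+00
1.268283e+04	1.000000e+00	0.000000e+00
1.314606e+04	1.000000e+00	0.000000e+00
1.362620e+04	1.000000e+00	0.000000e+00
1.412389e+04	1.000000e+00	0.000000e+00
1.463975e+04	1.000000e+00	0.000000e+00
1.517445e+04	1.000000e+00	0.000000e+00
1.572869e+04	1.000000e+00	0.000000e+00
1.630316e+04	1.000000e+00	0.000000e+00
1.689862e+04	1.000000e+00	0.000000e+00
1.751582e+04	1.000000e+00	0.000000e+00
1.815557e+04	1.000000e+00	0.000000e+00
1.881869e+04	1.000000e+00	0.000000e+00
1.950602e+04	1.000000e+00	0.000000e+00
2.021846e+04	1.000000e+00	0.000000e+00
2.095692e+04	1.000000e+00	0.000000e+00
2.172235e+04	1.000000e+00	0.000000e+00
2.251574e+04	1.000000e+00	0.000000e+00
2.333811e+04	1.000000e+00	0.000000e+00
2.419051e+04	1.000000e+00	0.000000e+00
2.507404e+04	1.000000e+00	0.000000e+00
2.598985e+04	1.000000e+00	0.000000e+00
2.693910e+04	1.000000e+00	0.000000e+00
2.792303e+04	1.000000e+00	0.000000e+00
2.894289e+04	1.000000e+00	0.000000e+00
3.000000e+04	1.000000e+00	0.000000e+00
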