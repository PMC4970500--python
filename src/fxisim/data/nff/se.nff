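# Se  Z=34  E(eV) f1 f2  (Cromer-Liberman, f1 = Z + f')
1.000000e+02	3.753491e+00	7.847945e+00
1.036524e+02	3.979137e+00	8.239537e+00
1.074382e+02	4.222061e+00	8.630291e+00
1.113623e+02	4.482943e+00	9.018283e+00
1.154297e+02	4.761970e+00	9.401520e+00
1.196456e+02	5.058818e+00	9.777955e+00
1.240156e+02	5.372603e+00	1.014551e+01
1.285451e+02	5.701767e+00	1.050208e+01
1.332401e+02	6.043877e+00	1.084557e+01
1.381066e+02	6.395249e+00	1.117392e+01
1.431508e+02	6.750208e+00	1.148509e+01
1.483792e+02	7.099534e+00	1.177711e+01
1.537987e+02	7.426706e+00	1.204811e+01
1.594160e+02	7.697266e+00	1.229632e+01
1.652385e+02	7.977983e+00	1.318523e+01
1.712737e+02	8.577541e+00	1.373669e+01
1.775293e+02	9.256231e+00	1.400562e+01
1.840134e+02	9.874765e+00	1.425114e+01
1.907343e+02	1.047817e+01	1.447197e+01
1.977007e+02	1.107529e+01	1.466691e+01
2.049215e+02	1.166647e+01	1.483490e+01
2.124061e+02	1.224717e+01	1.497502e+01
2.201640e+02	1.280647e+01	1.508647e+01
2.282053e+02	1.666767e+01	1.511159e+01
2.365403e+02	1.712076e+01	1.551319e+01
2.451797e+02	1.783668e+01	1.526086e+01
2.541346e+02	1.843296e+01	1.500549e+01
2.634167e+02	1.897979e+01	1.474699e+01
2.730377e+02	1.949452e+01	1.448523e+01
2.830101e+02	2.021972e+01	1.418022e+01
2.933468e+02	2.079987e+01	1.385187e+01
3.040610e+02	2.123611e+01	1.351934e+01
3.151666e+02	2.164747e+01	1.318576e+01
3.266777e+02	2.203557e+01	1.285162e+01
3.386093e+02	2.240169e+01	1.251740e+01
3.509767e+02	2.274691e+01	1.218358e+01
3.637958e+02	2.307212e+01	1.185057e+01
3.770831e+02	2.337811e+01	1.151879e+01
3.908557e+02	2.366559e+01	1.118863e+01
4.051313e+02	2.396630e+01	1.085500e+01
4.199283e+02	2.421666e+01	1.052407e+01
4.352658e+02	2.444955e+01	1.019632e+01
4.511635e+02	2.466553e+01	9.872079e+00
4.676418e+02	2.486506e+01	9.551626e+00
4.847219e+02	2.504856e+01	9.235238e+00
5.024259e+02	2.521641e+01	8.923166e+00
5.207766e+02	2.536893e+01	8.615643e+00
5.397974e+02	2.550639e+01	8.312887e+00
5.595130e+02	2.562902e+01	8.015096e+00
5.799487e+02	2.573698e+01	7.722454e+00
6.011308e+02	2.583039e+01	7.435129e+00
6.230865e+02	2.590931e+01	7.153275e+00
6.458441e+02	2.597376e+01	6.877034e+00
6.694330e+02	2.608768e+01	6.600682e+00
6.938833e+02	2.614694e+01	6.328379e+00
7.192268e+02	2.615600e+01	6.063590e+00
7.454958e+02	2.614948e+01	5.806790e+00
7.727244e+02	2.612700e+01	5.557954e+00
8.009474e+02	2.608795e+01	5.317035e+00
8.302012e+02	2.603147e+01	5.083969e+00
8.605235e+02	2.595636e+01	4.858678e+00
8.919533e+02	2.586103e+01	4.641067e+00
9.245310e+02	2.574327e+01	4.431030e+00
9.582986e+02	2.560093e+01	4.228393e+00
9.932996e+02	2.542839e+01	4.033175e+00
1.029579e+03	2.522066e+01	3.840780e+00
1.067183e+03	2.502611e+01	3.655393e+00
1.106161e+03	2.471691e+01	3.475539e+00
1.146563e+03	2.434050e+01	3.304018e+00
1.188440e+03	2.387298e+01	3.140447e+00
1.231846e+03	2.327348e+01	2.984462e+00
1.276838e+03	2.246340e+01	2.835716e+00
1.323474e+03	2.125727e+01	2.693879e+00
1.371812e+03	1.901285e+01	2.558639e+00
1.421916e+03	9.561111e+00	2.429695e+00
1.473850e+03	1.469872e+01	1.786140e+01
1.527681e+03	2.544830e+01	1.669363e+01
1.583479e+03	2.353409e+01	1.414334e+01
1.641314e+03	2.431195e+01	1.336801e+01
1.701261e+03	2.647928e+01	1.449663e+01
1.763398e+03	2.799021e+01	1.374774e+01
1.827804e+03	2.908876e+01	1.304594e+01
1.894563e+03	2.993321e+01	1.237900e+01
1.963760e+03	3.062961e+01	1.174751e+01
2.035485e+03	3.121686e+01	1.114438e+01
2.109829e+03	3.171039e+01	1.056748e+01
2.186888e+03	3.213047e+01	1.001550e+01
2.266762e+03	3.248416e+01	9.487738e+00
2.349554e+03	3.278442e+01	8.983949e+00
2.435369e+03	3.303916e+01	8.503303e+00
2.524318e+03	3.325474e+01	8.044982e+00
2.616517e+03	3.343642e+01	7.608182e+00
2.712082e+03	3.358858e+01	7.192114e+00
2.811139e+03	3.371493e+01	6.796001e+00
2.913813e+03	3.381924e+01	6.419029e+00
3.020237e+03	3.390449e+01	6.060105e+00
3.130548e+03	3.398069e+01	5.717046e+00
3.244888e+03	3.403316e+01	5.391916e+00
3.363405e+03	3.407148e+01	5.083654e+00
3.486250e+03	3.409288e+01	4.791509e+00
3.613582e+03	3.410388e+01	4.515178e+00
3.745564e+03	3.410585e+01	4.253874e+00
3.882368e+03	3.410000e+01	4.006845e+00
4.024167e+03	3.408733e+01	3.773370e+00
4.171146e+03	3.406874e+01	3.552763e+00
4.323493e+03	3.404500e+01	3.344366e+00
4.481405e+03	3.401669e+01	3.147556e+00
4.645084e+03	3.398459e+01	2.961730e+00
4.814741e+03	3.394910e+01	2.786317e+00
4.990595e+03	3.391065e+01	2.620771e+00
5.172871e+03	3.386962e+01	2.464575e+00
5.361806e+03	3.382630e+01	2.317233e+00
5.557640e+03	3.378096e+01	2.178275e+00
5.760628e+03	3.373378e+01	2.047252e+00
5.971029e+03	3.368491e+01	1.923740e+00
6.189115e+03	3.363444e+01	1.807331e+00
6.415167e+03	3.358541e+01	1.697465e+00
6.649475e+03	3.353130e+01	1.593891e+00
6.892340e+03	3.347557e+01	1.496418e+00
7.144076e+03	3.341808e+01	1.404700e+00
7.405007e+03	3.335960e+01	1.318314e+00
7.675468e+03	3.329766e+01	1.237079e+00
7.955807e+03	3.323303e+01	1.160707e+00
8.246385e+03	3.316513e+01	1.088915e+00
8.547576e+03	3.309318e+01	1.021436e+00
8.859768e+03	3.301615e+01	9.580203e-01
9.183363e+03	3.293328e+01	8.975496e-01
9.518776e+03	3.284164e+01	8.407337e-01
9.866441e+03	3.273835e+01	7.874764e-01
1.022680e+04	3.261916e+01	7.375559e-01
1.060033e+04	3.247723e+01	6.907644e-01
1.098749e+04	3.230072e+01	6.469066e-01
1.138880e+04	3.206668e+01	6.057995e-01
1.180477e+04	3.172149e+01	5.672714e-01
1.223592e+04	3.108314e+01	5.311614e-01
1.268283e+04	2.828940e+01	3.827806e+00
1.314606e+04	3.160272e+01	3.551589e+00
1.362620e+04	3.232179e+01	3.341001e+00
1.412389e+04	3.278404e+01	3.155391e+00
1.463975e+04	3.310779e+01	2.978864e+00
1.517445e+04	3.335106e+01	2.811047e+00
1.572869e+04	3.354098e+01	2.651580e+00
1.630316e+04	3.369265e+01	2.500114e+00
1.689862e+04	3.381863e+01	2.355473e+00
1.751582e+04	3.391831e+01	2.218153e+00
1.815557e+04	3.399983e+01	2.088132e+00
1.881869e+04	3.406656e+01	1.965068e+00
1.950602e+04	3.412107e+01	1.848627e+00
2.021846e+04	3.416538e+01	1.738493e+00
2.095692e+04	3.420109e+01	1.634361e+00
2.172235e+04	3.422952e+01	1.535939e+00
2.251574e+04	3.425174e+01	1.442947e+00
2.333811e+04	3.426867e+01	1.355118e+00
2.419051e+04	3.428105e+01	1.272195e+00
2.507404e+04	3.428953e+01	1.193932e+00
2.598985e+04	3.429482e+01	1.120072e+00
2.693910e+04	3.429725e+01	1.050333e+00
2.792303e+04	3.429748e+01	9.843032e-01
2.894289e+04	3.429510e+01	9.222193e-01
3.000000e+04	3.429078e+01	8.638586e-01
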