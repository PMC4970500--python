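# Zn  Z=30  E(eV) f1 f2  (Cromer-Liberman, f1 = Z + f')
1.000000e+02	7.010764e+00	1.147411e+01
1.036524e+02	7.488006e+00	1.150367e+01
1.074382e+02	7.947521e+00	1.151904e+01
1.113623e+02	8.392301e+00	1.152011e+01
1.154297e+02	8.822928e+00	1.150688e+01
1.196456e+02	9.238152e+00	1.147940e+01
1.240156e+02	9.634591e+00	1.143785e+01
1.285451e+02	1.000518e+01	1.138245e+01
1.332401e+02	1.033419e+01	1.131354e+01
1.381066e+02	1.062685e+01	1.170382e+01
1.431508e+02	1.120346e+01	1.162520e+01
1.483792e+02	1.137544e+01	1.155525e+01
1.537987e+02	1.479301e+01	1.145699e+01
1.594160e+02	1.510799e+01	1.124400e+01
1.652385e+02	1.540680e+01	1.103276e+01
1.712737e+02	1.569210e+01	1.082347e+01
1.775293e+02	1.596558e+01	1.061627e+01
1.840134e+02	1.622843e+01	1.041127e+01
1.907343e+02	1.648155e+01	1.020855e+01
1.977007e+02	1.672565e+01	1.000815e+01
2.049215e+02	1.696136e+01	9.810059e+00
2.124061e+02	1.718917e+01	9.614253e+00
2.201640e+02	1.740952e+01	9.420668e+00
2.282053e+02	1.762279e+01	9.229217e+00
2.365403e+02	1.786065e+01	9.035159e+00
2.451797e+02	1.805923e+01	8.842359e+00
2.541346e+02	1.825089e+01	8.651732e+00
2.634167e+02	1.843584e+01	8.463139e+00
2.730377e+02	1.861428e+01	8.276431e+00
2.830101e+02	1.878633e+01	8.091448e+00
2.933468e+02	1.895205e+01	7.908026e+00
3.040610e+02	1.911145e+01	7.725999e+00
3.151666e+02	1.926450e+01	7.545206e+00
3.266777e+02	1.941111e+01	7.365489e+00
3.386093e+02	1.955114e+01	7.186701e+00
3.509767e+02	2.011465e+01	6.993158e+00
3.637958e+02	2.022691e+01	6.775411e+00
3.770831e+02	2.032861e+01	6.561401e+00
3.908557e+02	2.041982e+01	6.351196e+00
4.051313e+02	2.050054e+01	6.144853e+00
4.199283e+02	2.057074e+01	5.942420e+00
4.352658e+02	2.063028e+01	5.743940e+00
4.511635e+02	2.067899e+01	5.549446e+00
4.676418e+02	2.071659e+01	5.358964e+00
4.847219e+02	2.074274e+01	5.172516e+00
5.024259e+02	2.075694e+01	4.990115e+00
5.207766e+02	2.075862e+01	4.811770e+00
5.397974e+02	2.074699e+01	4.637486e+00
5.595130e+02	2.073469e+01	4.466188e+00
5.799487e+02	2.069237e+01	4.298869e+00
6.011308e+02	2.063309e+01	4.135794e+00
6.230865e+02	2.055501e+01	3.976944e+00
6.458441e+02	2.045576e+01	3.822293e+00
6.694330e+02	2.033233e+01	3.671813e+00
6.938833e+02	2.018078e+01	3.525474e+00
7.192268e+02	1.999587e+01	3.383239e+00
7.454958e+02	1.977053e+01	3.245071e+00
7.727244e+02	1.949486e+01	3.110930e+00
8.009474e+02	1.915453e+01	2.980773e+00
8.302012e+02	1.872771e+01	2.854553e+00
8.605235e+02	1.817877e+01	2.732223e+00
8.919533e+02	1.744312e+01	2.613732e+00
9.245310e+02	1.638286e+01	2.499029e+00
9.582986e+02	1.460566e+01	2.388059e+00
9.932996e+02	1.008693e+01	2.280766e+00
1.029579e+03	9.315126e+00	3.212905e+01
1.067183e+03	2.833486e+01	2.175164e+01
1.106161e+03	1.793198e+01	1.555896e+01
1.146563e+03	1.988915e+01	1.462575e+01
1.188440e+03	2.023450e+01	1.375272e+01
1.231846e+03	2.264109e+01	1.473398e+01
1.276838e+03	2.403306e+01	1.394123e+01
1.323474e+03	2.505677e+01	1.320217e+01
1.371812e+03	2.571679e+01	1.254635e+01
1.421916e+03	2.640368e+01	1.193157e+01
1.473850e+03	2.698318e+01	1.134146e+01
1.527681e+03	2.747661e+01	1.077532e+01
1.583479e+03	2.791123e+01	1.022998e+01
1.641314e+03	2.828966e+01	9.705822e+00
1.701261e+03	2.859732e+01	9.203879e+00
1.763398e+03	2.886082e+01	8.724194e+00
1.827804e+03	2.908608e+01	8.266028e+00
1.894563e+03	2.927801e+01	7.828651e+00
1.963760e+03	2.944074e+01	7.411343e+00
2.035485e+03	2.957789e+01	7.013391e+00
2.109829e+03	2.970579e+01	6.632168e+00
2.186888e+03	2.979781e+01	6.268882e+00
2.266762e+03	2.987208e+01	5.923627e+00
2.349554e+03	2.993072e+01	5.595629e+00
2.435369e+03	2.997754e+01	5.283923e+00
2.524318e+03	3.000981e+01	4.987945e+00
2.616517e+03	3.003152e+01	4.707183e+00
2.712082e+03	3.004349e+01	4.440958e+00
2.811139e+03	3.004711e+01	4.188611e+00
2.913813e+03	3.004338e+01	3.949500e+00
3.020237e+03	3.003325e+01	3.722661e+00
3.130548e+03	3.001748e+01	3.506607e+00
3.244888e+03	2.999632e+01	3.302421e+00
3.363405e+03	2.997053e+01	3.109498e+00
3.486250e+03	2.994072e+01	2.927263e+00
3.613582e+03	2.990744e+01	2.755166e+00
3.745564e+03	2.987203e+01	2.592671e+00
3.882368e+03	2.983294e+01	2.439281e+00
4.024167e+03	2.979155e+01	2.294529e+00
4.171146e+03	2.974809e+01	2.157959e+00
4.323493e+03	2.970278e+01	2.029137e+00
4.481405e+03	2.965972e+01	1.907482e+00
4.645084e+03	2.961277e+01	1.792403e+00
4.814741e+03	2.956188e+01	1.683979e+00
4.990595e+03	2.950946e+01	1.581894e+00
5.172871e+03	2.945899e+01	1.485789e+00
5.361806e+03	2.940241e+01	1.395041e+00
5.557640e+03	2.934450e+01	1.309677e+00
5.760628e+03	2.928441e+01	1.229388e+00
5.971029e+03	2.922175e+01	1.153882e+00
6.189115e+03	2.915599e+01	1.082883e+00
6.415167e+03	2.908645e+01	1.016130e+00
6.649475e+03	2.901219e+01	9.533771e-01
6.892340e+03	2.893193e+01	8.943906e-01
7.144076e+03	2.884393e+01	8.389511e-01
7.405007e+03	2.874570e+01	7.868514e-01
7.675468e+03	2.863360e+01	7.378958e-01
7.955807e+03	2.850195e+01	6.918996e-01
8.246385e+03	2.834142e+01	6.486887e-01
8.547576e+03	2.813494e+01	6.080988e-01
8.859768e+03	2.784654e+01	5.699752e-01
9.183363e+03	2.737745e+01	5.337044e-01
9.518776e+03	2.619740e+01	4.996484e-01
9.866441e+03	2.685473e+01	3.731853e+00
1.022680e+04	2.797764e+01	3.490428e+00
1.060033e+04	2.856087e+01	3.298537e+00
1.098749e+04	2.894852e+01	3.115846e+00
1.138880e+04	2.923263e+01	2.941995e+00
1.180477e+04	2.945148e+01	2.776633e+00
1.223592e+04	2.962470e+01	2.619416e+00
1.268283e+04	2.977198e+01	2.469545e+00
1.314606e+04	2.988415e+01	2.326253e+00
1.362620e+04	2.997685e+01	2.190556e+00
1.412389e+04	3.005296e+01	2.062096e+00
1.463975e+04	3.011537e+01	1.940528e+00
1.517445e+04	3.016639e+01	1.825522e+00
1.572869e+04	3.020783e+01	1.716762e+00
1.630316e+04	3.024118e+01	1.613943e+00
1.689862e+04	3.026764e+01	1.516774e+00
1.751582e+04	3.028820e+01	1.424978e+00
1.815557e+04	3.030368e+01	1.338288e+00
1.881869e+04	3.031457e+01	1.256448e+00
1.950602e+04	3.032632e+01	1.179115e+00
2.021846e+04	3.032902e+01	1.105966e+00
2.095692e+04	3.033017e+01	1.037077e+00
2.172235e+04	3.032910e+01	9.722168e-01
2.251574e+04	3.032619e+01	9.111640e-01
2.333811e+04	3.032149e+01	8.537148e-01
2.419051e+04	3.031539e+01	7.996729e-01
2.507404e+04	3.030813e+01	7.488503e-01
2.598985e+04	3.029993e+01	7.010676e-01
2.693910e+04	3.029089e+01	6.561078e-01
2.792303e+04	3.028118e+01	6.137450e-01
2.894289e+04	3.027094e+01	5.739929e-01
3.000000e+04	3.026030e+01	5.366988e-01
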