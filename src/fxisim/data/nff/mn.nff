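# Mn  Z=25  E(eV) f1 f2  (Cromer-Liberman, f1 = Z + f')
1.000000e+02	1.018765e+01	5.809051e+00
1.036524e+02	1.037139e+01	5.810395e+00
1.074382e+02	1.055211e+01	5.808664e+00
1.113623e+02	1.073054e+01	5.803891e+00
1.154297e+02	1.090712e+01	5.796095e+00
1.196456e+02	1.108207e+01	5.785287e+00
1.240156e+02	1.125555e+01	5.771469e+00
1.285451e+02	1.142765e+01	5.754632e+00
1.332401e+02	1.159933e+01	5.734755e+00
1.381066e+02	1.286960e+01	5.685282e+00
1.431508e+02	1.300639e+01	5.603085e+00
1.483792e+02	1.311200e+01	5.520750e+00
1.537987e+02	1.321568e+01	5.441796e+00
1.594160e+02	1.331775e+01	5.365808e+00
1.652385e+02	1.341842e+01	5.292364e+00
1.712737e+02	1.351784e+01	5.221045e+00
1.775293e+02	1.361610e+01	5.151433e+00
1.840134e+02	1.371320e+01	5.083118e+00
1.907343e+02	1.380909e+01	5.015699e+00
1.977007e+02	1.442414e+01	4.924678e+00
2.049215e+02	1.450942e+01	4.807866e+00
2.124061e+02	1.458887e+01	4.692866e+00
2.201640e+02	1.466249e+01	4.579595e+00
2.282053e+02	1.473021e+01	4.467975e+00
2.365403e+02	1.479194e+01	4.357932e+00
2.451797e+02	1.484752e+01	4.249402e+00
2.541346e+02	1.489675e+01	4.142325e+00
2.634167e+02	1.493938e+01	4.036648e+00
2.730377e+02	1.497508e+01	3.932324e+00
2.830101e+02	1.500347e+01	3.829314e+00
2.933468e+02	1.502408e+01	3.727584e+00
3.040610e+02	1.503638e+01	3.627107e+00
3.151666e+02	1.503972e+01	3.527860e+00
3.266777e+02	1.503331e+01	3.429828e+00
3.386093e+02	1.503987e+01	3.332420e+00
3.509767e+02	1.501004e+01	3.234595e+00
3.637958e+02	1.496700e+01	3.138187e+00
3.770831e+02	1.490917e+01	3.043196e+00
3.908557e+02	1.483462e+01	2.949625e+00
4.051313e+02	1.474094e+01	2.857481e+00
4.199283e+02	1.462510e+01	2.766774e+00
4.352658e+02	1.448322e+01	2.677517e+00
4.511635e+02	1.431029e+01	2.589723e+00
4.676418e+02	1.409965e+01	2.503411e+00
4.847219e+02	1.384228e+01	2.418597e+00
5.024259e+02	1.352557e+01	2.335301e+00
5.207766e+02	1.313134e+01	2.253543e+00
5.397974e+02	1.263221e+01	2.173343e+00
5.595130e+02	1.198475e+01	2.094722e+00
5.799487e+02	1.111533e+01	2.017700e+00
6.011308e+02	9.887343e+00	1.942296e+00
6.230865e+02	8.013421e+00	1.868531e+00
6.458441e+02	2.927930e+00	1.145554e+01
6.694330e+02	8.765840e+00	1.556886e+01
6.938833e+02	1.226293e+01	1.481487e+01
7.192268e+02	1.428349e+01	1.408991e+01
7.454958e+02	1.559698e+01	1.339331e+01
7.727244e+02	1.563709e+01	1.447279e+01
8.009474e+02	1.784329e+01	1.380899e+01
8.302012e+02	1.903360e+01	1.317018e+01
8.605235e+02	1.995046e+01	1.255572e+01
8.919533e+02	2.070073e+01	1.196495e+01
9.245310e+02	2.133633e+01	1.139712e+01
9.582986e+02	2.186999e+01	1.085171e+01
9.932996e+02	2.232813e+01	1.032835e+01
1.029579e+03	2.272991e+01	9.825189e+00
1.067183e+03	2.307689e+01	9.341943e+00
1.106161e+03	2.343173e+01	8.873942e+00
1.146563e+03	2.368536e+01	8.420844e+00
1.188440e+03	2.390324e+01	7.988078e+00
1.231846e+03	2.409003e+01	7.574913e+00
1.276838e+03	2.424959e+01	7.180632e+00
1.323474e+03	2.439441e+01	6.803690e+00
1.371812e+03	2.450822e+01	6.443597e+00
1.421916e+03	2.460318e+01	6.100543e+00
1.473850e+03	2.468144e+01	5.773863e+00
1.527681e+03	2.474488e+01	5.462907e+00
1.583479e+03	2.479451e+01	5.167047e+00
1.641314e+03	2.483318e+01	4.885690e+00
1.701261e+03	2.486148e+01	4.618201e+00
1.763398e+03	2.488056e+01	4.363999e+00
1.827804e+03	2.489144e+01	4.122520e+00
1.894563e+03	2.489505e+01	3.893216e+00
1.963760e+03	2.489219e+01	3.675556e+00
2.035485e+03	2.488359e+01	3.469029e+00
2.109829e+03	2.486991e+01	3.273138e+00
2.186888e+03	2.485171e+01	3.087403e+00
2.266762e+03	2.482950e+01	2.911362e+00
2.349554e+03	2.480373e+01	2.744568e+00
2.435369e+03	2.477479e+01	2.586592e+00
2.524318e+03	2.474302e+01	2.437019e+00
2.616517e+03	2.471098e+01	2.295357e+00
2.712082e+03	2.467366e+01	2.161284e+00
2.811139e+03	2.463432e+01	2.034586e+00
2.913813e+03	2.459312e+01	1.914884e+00
3.020237e+03	2.455042e+01	1.801632e+00
3.130548e+03	2.451096e+01	1.693808e+00
3.244888e+03	2.446467e+01	1.592014e+00
3.363405e+03	2.441637e+01	1.496135e+00
3.486250e+03	2.436604e+01	1.405843e+00
3.613582e+03	2.431375e+01	1.320826e+00
3.745564e+03	2.425932e+01	1.240788e+00
3.882368e+03	2.420250e+01	1.165449e+00
4.024167e+03	2.414293e+01	1.094542e+00
4.171146e+03	2.408009e+01	1.027817e+00
4.323493e+03	2.401328e+01	9.650341e-01
4.481405e+03	2.394160e+01	9.059692e-01
4.645084e+03	2.386378e+01	8.504091e-01
4.814741e+03	2.377809e+01	7.981526e-01
4.990595e+03	2.368211e+01	7.490093e-01
5.172871e+03	2.357225e+01	7.027995e-01
5.361806e+03	2.344302e+01	6.593534e-01
5.557640e+03	2.328542e+01	6.185106e-01
5.760628e+03	2.308329e+01	5.801197e-01
5.971029e+03	2.280328e+01	5.440378e-01
6.189115e+03	2.235787e+01	5.101300e-01
6.415167e+03	2.134102e+01	4.782690e-01
6.649475e+03	2.145573e+01	3.833786e+00
6.892340e+03	2.280035e+01	3.584792e+00
7.144076e+03	2.344417e+01	3.390190e+00
7.405007e+03	2.386474e+01	3.204312e+00
7.675468e+03	2.417123e+01	3.026881e+00
7.955807e+03	2.440689e+01	2.857623e+00
8.246385e+03	2.459367e+01	2.696267e+00
8.547576e+03	2.474536e+01	2.542493e+00
8.859768e+03	2.486749e+01	2.396149e+00
9.183363e+03	2.496779e+01	2.257101e+00
9.518776e+03	2.505012e+01	2.125399e+00
9.866441e+03	2.511782e+01	2.000746e+00
1.022680e+04	2.517342e+01	1.882804e+00
1.060033e+04	2.521887e+01	1.771249e+00
1.098749e+04	2.525574e+01	1.665770e+00
1.138880e+04	2.528532e+01	1.566069e+00
1.180477e+04	2.530867e+01	1.471861e+00
1.223592e+04	2.532748e+01	1.382861e+00
1.268283e+04	2.534081e+01	1.298797e+00
1.314606e+04	2.535414e+01	1.219339e+00
1.362620e+04	2.535975e+01	1.143789e+00
1.412389e+04	2.536240e+01	1.072644e+00
1.463975e+04	2.536333e+01	1.005647e+00
1.517445e+04	2.536124e+01	9.425674e-01
1.572869e+04	2.535735e+01	8.832186e-01
1.630316e+04	2.535194e+01	8.273944e-01
1.689862e+04	2.534525e+01	7.748992e-01
1.751582e+04	2.533751e+01	7.255475e-01
1.815557e+04	2.532889e+01	6.791633e-01
1.881869e+04	2.531957e+01	6.355796e-01
1.950602e+04	2.530968e+01	5.946382e-01
2.021846e+04	2.529935e+01	5.561892e-01
2.095692e+04	2.528869e+01	5.200905e-01
2.172235e+04	2.527780e+01	4.862075e-01
2.251574e+04	2.526676e+01	4.544127e-01
2.333811e+04	2.525563e+01	4.245856e-01
2.419051e+04	2.524449e+01	3.966119e-01
2.507404e+04	2.523338e+01	3.703836e-01
2.598985e+04	2.522236e+01	3.457984e-01
2.693910e+04	2.521145e+01	3.227384e-01
2.792303e+04	2.520067e+01	3.010913e-01
2.894289e+04	2.519278e+01	2.806697e-01
3.000000e+04	2.518212e+01	2.614871e-01
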