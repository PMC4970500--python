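# C  Z=6  E(eV) f1 f2  (Cromer-Liberman, f1 = Z + f')
1.000000e+02	4.228596e+00	6.370331e-01
1.036524e+02	4.228806e+00	6.132658e-01
1.074382e+02	4.227607e+00	5.901747e-01
1.113623e+02	4.224966e+00	5.677503e-01
1.154297e+02	4.220835e+00	5.459827e-01
1.196456e+02	4.215154e+00	5.248617e-01
1.240156e+02	4.225977e+00	5.035186e-01
1.285451e+02	4.215505e+00	4.828309e-01
1.332401e+02	4.203270e+00	4.629026e-01
1.381066e+02	4.189131e+00	4.437058e-01
1.431508e+02	4.172916e+00	4.252141e-01
1.483792e+02	4.154415e+00	4.074021e-01
1.537987e+02	4.133372e+00	3.902457e-01
1.594160e+02	4.109474e+00	3.737218e-01
1.652385e+02	4.082338e+00	3.578083e-01
1.712737e+02	4.051490e+00	3.424840e-01
1.775293e+02	4.016338e+00	3.277288e-01
1.840134e+02	3.976137e+00	3.135233e-01
1.907343e+02	3.929932e+00	2.998488e-01
1.977007e+02	3.876485e+00	2.866876e-01
2.049215e+02	3.814154e+00	2.740224e-01
2.124061e+02	3.740714e+00	2.618368e-01
2.201640e+02	3.653068e+00	2.501148e-01
2.282053e+02	3.546760e+00	2.388413e-01
2.365403e+02	3.415114e+00	2.280014e-01
2.451797e+02	3.247624e+00	2.175809e-01
2.541346e+02	3.026662e+00	2.075661e-01
2.634167e+02	2.720062e+00	1.979437e-01
2.730377e+02	2.261881e+00	1.887008e-01
2.830101e+02	1.491362e+00	1.798250e-01
2.933468e+02	2.160452e+00	3.860276e+00
3.040610e+02	3.181425e+00	3.699348e+00
3.151666e+02	3.786169e+00	3.542518e+00
3.266777e+02	4.218235e+00	3.389837e+00
3.386093e+02	4.552583e+00	3.241344e+00
3.509767e+02	4.822808e+00	3.097069e+00
3.637958e+02	5.047102e+00	2.957031e+00
3.770831e+02	5.240822e+00	2.821053e+00
3.908557e+02	5.402358e+00	2.689310e+00
4.051313e+02	5.541477e+00	2.561840e+00
4.199283e+02	5.661935e+00	2.438621e+00
4.352658e+02	5.766591e+00	2.319624e+00
4.511635e+02	5.857684e+00	2.204814e+00
4.676418e+02	5.937011e+00	2.094147e+00
4.847219e+02	6.045831e+00	1.985455e+00
5.024259e+02	6.101896e+00	1.876672e+00
5.207766e+02	6.149523e+00	1.773178e+00
5.397974e+02	6.189817e+00	1.674759e+00
5.595130e+02	6.223709e+00	1.581204e+00
5.799487e+02	6.251993e+00	1.492310e+00
6.011308e+02	6.275356e+00	1.407881e+00
6.230865e+02	6.294392e+00	1.327726e+00
6.458441e+02	6.309623e+00	1.251661e+00
6.694330e+02	6.321504e+00	1.179506e+00
6.938833e+02	6.330437e+00	1.111090e+00
7.192268e+02	6.336778e+00	1.046247e+00
7.454958e+02	6.340842e+00	9.848142e-01
7.727244e+02	6.342910e+00	9.266376e-01
8.009474e+02	6.343230e+00	8.715674e-01
8.302012e+02	6.342028e+00	8.194594e-01
8.605235e+02	6.339500e+00	7.701748e-01
8.919533e+02	6.335827e+00	7.235799e-01
9.245310e+02	6.331166e+00	6.795463e-01
9.582986e+02	6.325662e+00	6.379505e-01
9.932996e+02	6.319441e+00	5.986737e-01
1.029579e+03	6.312454e+00	5.615272e-01
1.067183e+03	6.304942e+00	5.265081e-01
1.106161e+03	6.297038e+00	4.935256e-01
1.146563e+03	6.292322e+00	4.623751e-01
1.188440e+03	6.283549e+00	4.328428e-01
1.231846e+03	6.274617e+00	4.050984e-01
1.276838e+03	6.265589e+00	3.790403e-01
1.323474e+03	6.256519e+00	3.545722e-01
1.371812e+03	6.247454e+00	3.316029e-01
1.421916e+03	6.238435e+00	3.100462e-01
1.473850e+03	6.229496e+00	2.898204e-01
1.527681e+03	6.220666e+00	2.708481e-01
1.583479e+03	6.211972e+00	2.530562e-01
1.641314e+03	6.203434e+00	2.363755e-01
1.701261e+03	6.195070e+00	2.207406e-01
1.763398e+03	6.186896e+00	2.060898e-01
1.827804e+03	6.178922e+00	1.923644e-01
1.894563e+03	6.171159e+00	1.795095e-01
1.963760e+03	6.163614e+00	1.674727e-01
2.035485e+03	6.156292e+00	1.562051e-01
2.109829e+03	6.149197e+00	1.456600e-01
2.186888e+03	6.142332e+00	1.357937e-01
2.266762e+03	6.135697e+00	1.265649e-01
2.349554e+03	6.129293e+00	1.179345e-01
2.435369e+03	6.123117e+00	1.098658e-01
2.524318e+03	6.117170e+00	1.023242e-01
2.616517e+03	6.111446e+00	9.527704e-02
2.712082e+03	6.105944e+00	8.869359e-02
2.811139e+03	6.100660e+00	8.254490e-02
2.913813e+03	6.095589e+00	7.680373e-02
3.020237e+03	6.090723e+00	7.143991e-02
3.130548e+03	6.086047e+00	6.641777e-02
3.244888e+03	6.081568e+00	6.173609e-02
3.363405e+03	6.077283e+00	5.737271e-02
3.486250e+03	6.073187e+00	5.330685e-02
3.613582e+03	6.069273e+00	4.951901e-02
3.745564e+03	6.065537e+00	4.599095e-02
3.882368e+03	6.061973e+00	4.270552e-02
4.024167e+03	6.058574e+00	3.964670e-02
4.171146e+03	6.055335e+00	3.679946e-02
4.323493e+03	6.052250e+00	3.414972e-02
4.481405e+03	6.049314e+00	3.168430e-02
4.645084e+03	6.046520e+00	2.939087e-02
4.814741e+03	6.043864e+00	2.725788e-02
4.990595e+03	6.041339e+00	2.527452e-02
5.172871e+03	6.038940e+00	2.343069e-02
5.361806e+03	6.036825e+00	2.171544e-02
5.557640e+03	6.034640e+00	2.011557e-02
5.760628e+03	6.032569e+00	1.863083e-02
5.971029e+03	6.030606e+00	1.725314e-02
6.189115e+03	6.028746e+00	1.597498e-02
6.415167e+03	6.026985e+00	1.478932e-02
6.649475e+03	6.025317e+00	1.368966e-02
6.892340e+03	6.023738e+00	1.266989e-02
7.144076e+03	6.022245e+00	1.172436e-02
7.405007e+03	6.020833e+00	1.084779e-02
7.675468e+03	6.019498e+00	1.003529e-02
7.955807e+03	6.018236e+00	9.282270e-03
8.246385e+03	6.017044e+00	8.584492e-03
8.547576e+03	6.015919e+00	7.937999e-03
8.859768e+03	6.014856e+00	7.339111e-03
9.183363e+03	6.013866e+00	6.778287e-03
9.518776e+03	6.012923e+00	6.259024e-03
9.866441e+03	6.012032e+00	5.779126e-03
1.022680e+04	6.011190e+00	5.335642e-03
1.060033e+04	6.010396e+00	4.925837e-03
1.098749e+04	6.009647e+00	4.547181e-03
1.138880e+04	6.008940e+00	4.197332e-03
1.180477e+04	6.008275e+00	3.874123e-03
1.223592e+04	6.007647e+00	3.575545e-03
1.268283e+04	6.007057e+00	3.299743e-03
1.314606e+04	6.006501e+00	3.044996e-03
1.362620e+04	6.005978e+00	2.809715e-03
1.412389e+04	6.005486e+00	2.592429e-03
1.463975e+04	6.005023e+00	2.391774e-03
1.517445e+04	6.004587e+00	2.206492e-03
1.572869e+04	6.004178e+00	2.035417e-03
1.630316e+04	6.003794e+00	1.877472e-03
1.689862e+04	6.003432e+00	1.731659e-03
1.751582e+04	6.003093e+00	1.597056e-03
1.815557e+04	6.002774e+00	1.472811e-03
1.881869e+04	6.002475e+00	1.358133e-03
1.950602e+04	6.002194e+00	1.252296e-03
2.021846e+04	6.001930e+00	1.154623e-03
2.095692e+04	6.001682e+00	1.064492e-03
2.172235e+04	6.001450e+00	9.813269e-04
2.251574e+04	6.001232e+00	9.045941e-04
2.333811e+04	6.001027e+00	8.338015e-04
2.419051e+04	6.000835e+00	7.684941e-04
2.507404e+04	6.000655e+00	7.082512e-04
2.598985e+04	6.000487e+00	6.526840e-04
2.693910e+04	6.000328e+00	6.012258e-04
2.792303e+04	6.000180e+00	5.532389e-04
2.894289e+04	6.000041e+00	5.090925e-04
3.000000e+04	5.999910e+00	4.684782e-04
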