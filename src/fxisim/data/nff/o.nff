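# O  Z=8  E(eV) f1 f2  (Cromer-Liberman, f1 = Z + f')
1.000000e+02	6.052284e+00	1.956310e+00
1.036524e+02	6.090297e+00	1.892470e+00
1.074382e+02	6.125567e+00	1.829531e+00
1.113623e+02	6.158180e+00	1.767555e+00
1.154297e+02	6.188222e+00	1.706601e+00
1.196456e+02	6.215776e+00	1.646720e+00
1.240156e+02	6.240920e+00	1.587960e+00
1.285451e+02	6.263731e+00	1.530362e+00
1.332401e+02	6.284048e+00	1.473965e+00
1.381066e+02	6.514304e+00	1.407564e+00
1.431508e+02	6.515522e+00	1.343889e+00
1.483792e+02	6.515217e+00	1.283033e+00
1.537987e+02	6.513488e+00	1.224866e+00
1.594160e+02	6.510419e+00	1.169268e+00
1.652385e+02	6.506079e+00	1.116122e+00
1.712737e+02	6.500521e+00	1.065317e+00
1.775293e+02	6.493786e+00	1.016748e+00
1.840134e+02	6.485899e+00	9.703121e-01
1.907343e+02	6.476873e+00	9.259138e-01
1.977007e+02	6.466707e+00	8.834608e-01
2.049215e+02	6.455382e+00	8.428654e-01
2.124061e+02	6.442870e+00	8.040441e-01
2.201640e+02	6.429121e+00	7.669171e-01
2.282053e+02	6.414071e+00	7.314088e-01
2.365403e+02	6.397635e+00	6.974469e-01
2.451797e+02	6.379706e+00	6.649629e-01
2.541346e+02	6.360153e+00	6.338912e-01
2.634167e+02	6.338814e+00	6.041698e-01
2.730377e+02	6.315492e+00	5.757395e-01
2.830101e+02	6.289949e+00	5.485438e-01
2.933468e+02	6.261893e+00	5.225294e-01
3.040610e+02	6.230970e+00	4.976451e-01
3.151666e+02	6.196743e+00	4.738425e-01
3.266777e+02	6.158671e+00	4.510753e-01
3.386093e+02	6.116077e+00	4.292996e-01
3.509767e+02	6.068104e+00	4.084734e-01
3.637958e+02	6.013645e+00	3.885568e-01
3.770831e+02	5.951254e+00	3.695119e-01
3.908557e+02	5.878993e+00	3.513023e-01
4.051313e+02	5.794205e+00	3.338934e-01
4.199283e+02	5.693134e+00	3.172523e-01
4.352658e+02	5.570276e+00	3.013473e-01
4.511635e+02	5.427146e+00	2.859433e-01
4.676418e+02	5.229361e+00	2.709463e-01
4.847219e+02	4.963907e+00	2.566851e-01
5.024259e+02	4.585044e+00	2.431256e-01
5.207766e+02	3.991765e+00	2.302352e-01
5.397974e+02	3.097240e+00	4.096331e+00
5.595130e+02	4.816859e+00	3.916632e+00
5.799487e+02	5.602358e+00	3.741601e+00
6.011308e+02	6.122302e+00	3.571318e+00
6.230865e+02	6.509398e+00	3.405850e+00
6.458441e+02	6.814674e+00	3.245248e+00
6.694330e+02	7.063538e+00	3.089550e+00
6.938833e+02	7.270662e+00	2.938780e+00
7.192268e+02	7.445384e+00	2.792950e+00
7.454958e+02	7.594073e+00	2.652059e+00
7.727244e+02	7.721308e+00	2.516093e+00
8.009474e+02	7.830518e+00	2.385029e+00
8.302012e+02	7.924357e+00	2.258831e+00
8.605235e+02	8.004935e+00	2.137453e+00
8.919533e+02	8.073953e+00	2.020841e+00
9.245310e+02	8.138683e+00	1.908120e+00
9.582986e+02	8.185806e+00	1.800703e+00
9.932996e+02	8.225347e+00	1.698701e+00
1.029579e+03	8.258942e+00	1.601345e+00
1.067183e+03	8.286439e+00	1.508944e+00
1.106161e+03	8.308625e+00	1.421401e+00
1.146563e+03	8.326256e+00	1.338491e+00
1.188440e+03	8.339943e+00	1.259996e+00
1.231846e+03	8.350203e+00	1.185709e+00
1.276838e+03	8.357478e+00	1.115430e+00
1.323474e+03	8.362153e+00	1.048967e+00
1.371812e+03	8.364567e+00	9.861339e-01
1.421916e+03	8.365016e+00	9.267552e-01
1.473850e+03	8.363763e+00	8.706610e-01
1.527681e+03	8.361039e+00	8.176888e-01
1.583479e+03	8.357050e+00	7.676828e-01
1.641314e+03	8.351980e+00	7.204939e-01
1.701261e+03	8.345990e+00	6.759796e-01
1.763398e+03	8.339226e+00	6.340033e-01
1.827804e+03	8.331815e+00	5.944347e-01
1.894563e+03	8.323872e+00	5.571490e-01
1.963760e+03	8.315498e+00	5.220272e-01
2.035485e+03	8.306783e+00	4.889557e-01
2.109829e+03	8.297804e+00	4.578258e-01
2.186888e+03	8.290277e+00	4.284121e-01
2.266762e+03	8.280707e+00	4.007478e-01
2.349554e+03	8.271086e+00	3.747761e-01
2.435369e+03	8.261466e+00	3.504000e-01
2.524318e+03	8.251888e+00	3.275273e-01
2.616517e+03	8.242392e+00	3.060709e-01
2.712082e+03	8.233008e+00	2.859486e-01
2.811139e+03	8.223764e+00	2.670822e-01
2.913813e+03	8.214683e+00	2.493980e-01
3.020237e+03	8.205802e+00	2.328014e-01
3.130548e+03	8.197162e+00	2.171583e-01
3.244888e+03	8.188733e+00	2.025231e-01
3.363405e+03	8.180464e+00	1.888335e-01
3.486250e+03	8.172409e+00	1.760319e-01
3.613582e+03	8.164582e+00	1.640633e-01
3.745564e+03	8.156989e+00	1.528760e-01
3.882368e+03	8.149638e+00	1.424212e-01
4.024167e+03	8.142530e+00	1.326532e-01
4.171146e+03	8.135668e+00	1.235288e-01
4.323493e+03	8.129051e+00	1.150075e-01
4.481405e+03	8.122679e+00	1.070512e-01
4.645084e+03	8.116549e+00	9.962408e-02
4.814741e+03	8.110657e+00	9.269248e-02
4.990595e+03	8.105000e+00	8.622475e-02
5.172871e+03	8.099574e+00	8.019119e-02
5.361806e+03	8.094373e+00	7.456390e-02
5.557640e+03	8.089392e+00	6.931668e-02
5.760628e+03	8.084626e+00	6.442495e-02
5.971029e+03	8.080068e+00	5.986563e-02
6.189115e+03	8.075712e+00	5.561706e-02
6.415167e+03	8.071552e+00	5.165896e-02
6.649475e+03	8.067582e+00	4.797227e-02
6.892340e+03	8.063795e+00	4.453915e-02
7.144076e+03	8.060186e+00	4.134286e-02
7.405007e+03	8.056747e+00	3.836773e-02
7.675468e+03	8.053472e+00	3.559906e-02
7.955807e+03	8.050355e+00	3.302311e-02
8.246385e+03	8.047390e+00	3.062698e-02
8.547576e+03	8.044571e+00	2.839862e-02
8.859768e+03	8.041893e+00	2.632674e-02
9.183363e+03	8.039335e+00	2.439915e-02
9.518776e+03	8.036906e+00	2.260884e-02
9.866441e+03	8.034601e+00	2.094662e-02
1.022680e+04	8.032676e+00	1.939439e-02
1.060033e+04	8.030578e+00	1.795067e-02
1.098749e+04	8.028604e+00	1.661254e-02
1.138880e+04	8.026722e+00	1.537249e-02
1.180477e+04	8.024941e+00	1.422355e-02
1.223592e+04	8.023256e+00	1.315916e-02
1.268283e+04	8.021663e+00	1.217318e-02
1.314606e+04	8.020158e+00	1.125993e-02
1.362620e+04	8.018735e+00	1.041415e-02
1.412389e+04	8.017392e+00	9.630911e-03
1.463975e+04	8.016123e+00	8.905677e-03
1.517445e+04	8.014926e+00	8.234220e-03
1.572869e+04	8.013797e+00	7.612615e-03
1.630316e+04	8.012731e+00	7.037220e-03
1.689862e+04	8.011726e+00	6.504655e-03
1.751582e+04	8.010779e+00	6.011782e-03
1.815557e+04	8.009886e+00	5.555691e-03
1.881869e+04	8.009045e+00	5.133680e-03
1.950602e+04	8.008252e+00	4.743242e-03
2.021846e+04	8.007506e+00	4.382053e-03
2.095692e+04	8.006803e+00	4.047956e-03
2.172235e+04	8.006142e+00	3.738951e-03
2.251574e+04	8.005520e+00	3.453183e-03
2.333811e+04	8.004934e+00	3.188931e-03
2.419051e+04	8.004383e+00	2.944601e-03
2.507404e+04	8.003865e+00	2.718715e-03
2.598985e+04	8.003378e+00	2.509901e-03
2.693910e+04	8.002921e+00	2.316188e-03
2.792303e+04	8.002491e+00	2.135359e-03
2.894289e+04	8.002087e+00	1.968606e-03
3.000000e+04	8.001707e+00	1.814836e-03
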