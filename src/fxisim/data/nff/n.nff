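# N  Z=7  E(eV) f1 f2  (Cromer-Liberman, f1 = Z + f')
1.000000e+02	5.179244e+00	1.185279e+00
1.036524e+02	5.196105e+00	1.149528e+00
1.074382e+02	5.301162e+00	1.109263e+00
1.113623e+02	5.312025e+00	1.066393e+00
1.154297e+02	5.321127e+00	1.024795e+00
1.196456e+02	5.328533e+00	9.844541e-01
1.240156e+02	5.334299e+00	9.453520e-01
1.285451e+02	5.338469e+00	9.074704e-01
1.332401e+02	5.341079e+00	8.707896e-01
1.381066e+02	5.342151e+00	8.352893e-01
1.431508e+02	5.341700e+00	8.009481e-01
1.483792e+02	5.339729e+00	7.677442e-01
1.537987e+02	5.336227e+00	7.356550e-01
1.594160e+02	5.331172e+00	7.046575e-01
1.652385e+02	5.324528e+00	6.747283e-01
1.712737e+02	5.316245e+00	6.458435e-01
1.775293e+02	5.336781e+00	6.167246e-01
1.840134e+02	5.322416e+00	5.884567e-01
1.907343e+02	5.306277e+00	5.614175e-01
1.977007e+02	5.288224e+00	5.355520e-01
2.049215e+02	5.268080e+00	5.108075e-01
2.124061e+02	5.245629e+00	4.871344e-01
2.201640e+02	5.220603e+00	4.644853e-01
2.282053e+02	5.192672e+00	4.428154e-01
2.365403e+02	5.161428e+00	4.220820e-01
2.451797e+02	5.126363e+00	4.022445e-01
2.541346e+02	5.086839e+00	3.832644e-01
2.634167e+02	5.042048e+00	3.651051e-01
2.730377e+02	4.990951e+00	3.477317e-01
2.830101e+02	4.932185e+00	3.311110e-01
2.933468e+02	4.863934e+00	3.152114e-01
3.040610e+02	4.783715e+00	3.000028e-01
3.151666e+02	4.688035e+00	2.854564e-01
3.266777e+02	4.571805e+00	2.715449e-01
3.386093e+02	4.427290e+00	2.582422e-01
3.509767e+02	4.242076e+00	2.455233e-01
3.637958e+02	3.994823e+00	2.333644e-01
3.770831e+02	3.645269e+00	2.217426e-01
3.908557e+02	3.106829e+00	2.106362e-01
4.051313e+02	1.447441e+00	4.042568e+00
4.199283e+02	3.628368e+00	3.869432e+00
4.352658e+02	4.471795e+00	3.700801e+00
4.511635e+02	5.013490e+00	3.536737e+00
4.676418e+02	5.412054e+00	3.377286e+00
4.847219e+02	5.724691e+00	3.222482e+00
5.024259e+02	5.982734e+00	3.072254e+00
5.207766e+02	6.194000e+00	2.926630e+00
5.397974e+02	6.372389e+00	2.785725e+00
5.595130e+02	6.524516e+00	2.649526e+00
5.799487e+02	6.655099e+00	2.518008e+00
6.011308e+02	6.767647e+00	2.391140e+00
6.230865e+02	6.864859e+00	2.268881e+00
6.458441e+02	6.948870e+00	2.151180e+00
6.694330e+02	7.021411e+00	2.037981e+00
6.938833e+02	7.105001e+00	1.926878e+00
7.192268e+02	7.155433e+00	1.819594e+00
7.454958e+02	7.198000e+00	1.717594e+00
7.727244e+02	7.233719e+00	1.620660e+00
8.009474e+02	7.263454e+00	1.528582e+00
8.302012e+02	7.287947e+00	1.441157e+00
8.605235e+02	7.307842e+00	1.358185e+00
8.919533e+02	7.323698e+00	1.279476e+00
9.245310e+02	7.336004e+00	1.204843e+00
9.582986e+02	7.345192e+00	1.134107e+00
9.932996e+02	7.351642e+00	1.067094e+00
1.029579e+03	7.355620e+00	1.003085e+00
1.067183e+03	7.357366e+00	9.425054e-01
1.106161e+03	7.357198e+00	8.853203e-01
1.146563e+03	7.355389e+00	8.313566e-01
1.188440e+03	7.352177e+00	7.804491e-01
1.231846e+03	7.347771e+00	7.324402e-01
1.276838e+03	7.342352e+00	6.871791e-01
1.323474e+03	7.336081e+00	6.445223e-01
1.371812e+03	7.329101e+00	6.043327e-01
1.421916e+03	7.321536e+00	5.664798e-01
1.473850e+03	7.313496e+00	5.308390e-01
1.527681e+03	7.305078e+00	4.972918e-01
1.583479e+03	7.296369e+00	4.657253e-01
1.641314e+03	7.289546e+00	4.359078e-01
1.701261e+03	7.280223e+00	4.078180e-01
1.763398e+03	7.270821e+00	3.814456e-01
1.827804e+03	7.261395e+00	3.566920e-01
1.894563e+03	7.251990e+00	3.334636e-01
1.963760e+03	7.242646e+00	3.116722e-01
2.035485e+03	7.233398e+00	2.912339e-01
2.109829e+03	7.224274e+00	2.720697e-01
2.186888e+03	7.215301e+00	2.541047e-01
2.266762e+03	7.206498e+00	2.372682e-01
2.349554e+03	7.197883e+00	2.214933e-01
2.435369e+03	7.189470e+00	2.067169e-01
2.524318e+03	7.181271e+00	1.928792e-01
2.616517e+03	7.173294e+00	1.799239e-01
2.712082e+03	7.165547e+00	1.677980e-01
2.811139e+03	7.158035e+00	1.564510e-01
2.913813e+03	7.150760e+00	1.458359e-01
3.020237e+03	7.143725e+00	1.358947e-01
3.130548e+03	7.136924e+00	1.265506e-01
3.244888e+03	7.130356e+00	1.178248e-01
3.363405e+03	7.124022e+00	1.096783e-01
3.486250e+03	7.117922e+00	1.020741e-01
3.613582e+03	7.112053e+00	9.497766e-02
3.745564e+03	7.106412e+00	8.835649e-02
3.882368e+03	7.100998e+00	8.218006e-02
4.024167e+03	7.095804e+00	7.641973e-02
4.171146e+03	7.090827e+00	7.104860e-02
4.323493e+03	7.086064e+00	6.604136e-02
4.481405e+03	7.081504e+00	6.137444e-02
4.645084e+03	7.077144e+00	5.702563e-02
4.814741e+03	7.072979e+00	5.297410e-02
4.990595e+03	7.069002e+00	4.920033e-02
5.172871e+03	7.065208e+00	4.568603e-02
5.361806e+03	7.061589e+00	4.241405e-02
5.557640e+03	7.058141e+00	3.936832e-02
5.760628e+03	7.054856e+00	3.653381e-02
5.971029e+03	7.051729e+00	3.389643e-02
6.189115e+03	7.048754e+00	3.144298e-02
6.415167e+03	7.045925e+00	2.916113e-02
6.649475e+03	7.043235e+00	2.703932e-02
6.892340e+03	7.040680e+00	2.506675e-02
7.144076e+03	7.038253e+00	2.323330e-02
7.405007e+03	7.035950e+00	2.152954e-02
7.675468e+03	7.033801e+00	1.994565e-02
7.955807e+03	7.031717e+00	1.847421e-02
8.246385e+03	7.029742e+00	1.710863e-02
8.547576e+03	7.027871e+00	1.584150e-02
8.859768e+03	7.026100e+00	1.466590e-02
9.183363e+03	7.024457e+00	1.356424e-02
9.518776e+03	7.022891e+00	1.254267e-02
9.866441e+03	7.021399e+00	1.159701e-02
1.022680e+04	7.019982e+00	1.072170e-02
1.060033e+04	7.018639e+00	9.911572e-03
1.098749e+04	7.017367e+00	9.161848e-03
1.138880e+04	7.016164e+00	8.468083e-03
1.180477e+04	7.015027e+00	7.826157e-03
1.223592e+04	7.013955e+00	7.232234e-03
1.268283e+04	7.012941e+00	6.682783e-03
1.314606e+04	7.011985e+00	6.174529e-03
1.362620e+04	7.011083e+00	5.704426e-03
1.412389e+04	7.010232e+00	5.269648e-03
1.463975e+04	7.009431e+00	4.867577e-03
1.517445e+04	7.008676e+00	4.495786e-03
1.572869e+04	7.007965e+00	4.152025e-03
1.630316e+04	7.007295e+00	3.834210e-03
1.689862e+04	7.006665e+00	3.540409e-03
1.751582e+04	7.006071e+00	3.268831e-03
1.815557e+04	7.005513e+00	3.017818e-03
1.881869e+04	7.004988e+00	2.785834e-03
1.950602e+04	7.004494e+00	2.571455e-03
2.021846e+04	7.004030e+00	2.373363e-03
2.095692e+04	7.003594e+00	2.190337e-03
2.172235e+04	7.003184e+00	2.021246e-03
2.251574e+04	7.002798e+00	1.865044e-03
2.333811e+04	7.002436e+00	1.720761e-03
2.419051e+04	7.002096e+00	1.587499e-03
2.507404e+04	7.001777e+00	1.464427e-03
2.598985e+04	7.001477e+00	1.350778e-03
2.693910e+04	7.001196e+00	1.245475e-03
2.792303e+04	7.000932e+00	1.147326e-03
2.894289e+04	7.000684e+00	1.056900e-03
3.000000e+04	7.000451e+00	9.735892e-04
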