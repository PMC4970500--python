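# Fe  Z=26  E(eV) f1 f2  (Cromer-Liberman, f1 = Z + f')
1.000000e+02	1.163634e+01	6.389282e+00
1.036524e+02	1.183155e+01	6.328037e+00
1.074382e+02	1.200910e+01	6.268161e+00
1.113623e+02	1.217597e+01	6.209669e+00
1.154297e+02	1.233549e+01	6.152550e+00
1.196456e+02	1.248952e+01	6.096763e+00
1.240156e+02	1.263928e+01	6.042239e+00
1.285451e+02	1.278564e+01	5.988885e+00
1.332401e+02	1.292921e+01	5.936582e+00
1.381066e+02	1.307048e+01	5.885186e+00
1.431508e+02	1.320983e+01	5.834532e+00
1.483792e+02	1.334754e+01	5.784436e+00
1.537987e+02	1.348385e+01	5.734694e+00
1.594160e+02	1.364756e+01	5.682891e+00
1.652385e+02	1.378048e+01	5.628283e+00
1.712737e+02	1.391172e+01	5.573712e+00
1.775293e+02	1.404136e+01	5.518955e+00
1.840134e+02	1.416943e+01	5.463782e+00
1.907343e+02	1.429591e+01	5.407959e+00
1.977007e+02	1.442073e+01	5.351253e+00
2.049215e+02	1.454377e+01	5.293433e+00
2.124061e+02	1.466487e+01	5.234272e+00
2.201640e+02	1.529972e+01	5.146458e+00
2.282053e+02	1.540774e+01	5.034526e+00
2.365403e+02	1.550899e+01	4.922755e+00
2.451797e+02	1.560339e+01	4.811206e+00
2.541346e+02	1.569085e+01	4.699941e+00
2.634167e+02	1.577122e+01	4.589023e+00
2.730377e+02	1.584434e+01	4.478512e+00
2.830101e+02	1.590997e+01	4.368469e+00
2.933468e+02	1.596785e+01	4.258955e+00
3.040610e+02	1.601764e+01	4.150030e+00
3.151666e+02	1.605895e+01	4.041755e+00
3.266777e+02	1.609133e+01	3.934191e+00
3.386093e+02	1.611423e+01	3.827398e+00
3.509767e+02	1.612700e+01	3.721435e+00
3.637958e+02	1.612887e+01	3.616363e+00
3.770831e+02	1.614036e+01	3.511378e+00
3.908557e+02	1.611645e+01	3.406303e+00
4.051313e+02	1.607818e+01	3.302509e+00
4.199283e+02	1.602394e+01	3.200050e+00
4.352658e+02	1.595174e+01	3.098976e+00
4.511635e+02	1.585912e+01	2.999339e+00
4.676418e+02	1.574293e+01	2.901186e+00
4.847219e+02	1.559916e+01	2.804566e+00
5.024259e+02	1.542255e+01	2.709524e+00
5.207766e+02	1.520611e+01	2.616104e+00
5.397974e+02	1.494028e+01	2.524346e+00
5.595130e+02	1.461163e+01	2.434290e+00
5.799487e+02	1.420060e+01	2.345974e+00
6.011308e+02	1.367748e+01	2.259432e+00
6.230865e+02	1.299457e+01	2.174695e+00
6.458441e+02	1.206977e+01	2.091794e+00
6.694330e+02	1.074760e+01	2.010754e+00
6.938833e+02	8.690997e+00	1.931599e+00
7.192268e+02	5.812725e+00	1.147524e+01
7.454958e+02	1.078544e+01	1.554256e+01
7.727244e+02	1.389189e+01	1.475825e+01
8.009474e+02	1.574184e+01	1.400854e+01
8.302012e+02	1.691984e+01	1.329217e+01
8.605235e+02	1.773138e+01	1.438233e+01
8.919533e+02	1.934747e+01	1.370164e+01
9.245310e+02	2.043882e+01	1.305004e+01
9.582986e+02	2.129796e+01	1.242645e+01
9.932996e+02	2.200471e+01	1.182983e+01
1.029579e+03	2.262220e+01	1.126419e+01
1.067183e+03	2.312942e+01	1.072120e+01
1.106161e+03	2.356579e+01	1.019949e+01
1.146563e+03	2.394270e+01	9.698545e+00
1.188440e+03	2.426895e+01	9.217847e+00
1.231846e+03	2.460633e+01	8.750639e+00
1.276838e+03	2.484551e+01	8.300576e+00
1.323474e+03	2.505128e+01	7.870890e+00
1.371812e+03	2.522814e+01	7.460836e+00
1.421916e+03	2.538029e+01	7.069681e+00
1.473850e+03	2.552238e+01	6.695179e+00
1.527681e+03	2.564117e+01	6.338133e+00
1.583479e+03	2.578949e+01	5.998152e+00
1.641314e+03	2.561481e+01	5.674558e+00
1.701261e+03	2.577564e+01	5.366686e+00
1.763398e+03	2.583650e+01	5.073904e+00
1.827804e+03	2.587627e+01	4.795591e+00
1.894563e+03	2.590283e+01	4.531126e+00
1.963760e+03	2.591913e+01	4.279919e+00
2.035485e+03	2.592685e+01	4.041401e+00
2.109829e+03	2.592718e+01	3.815016e+00
2.186888e+03	2.592107e+01	3.600231e+00
2.266762e+03	2.590933e+01	3.396526e+00
2.349554e+03	2.589261e+01	3.203402e+00
2.435369e+03	2.587153e+01	3.020376e+00
2.524318e+03	2.584658e+01	2.846983e+00
2.616517e+03	2.581820e+01	2.682773e+00
2.712082e+03	2.578680e+01	2.527316e+00
2.811139e+03	2.575269e+01	2.380194e+00
2.913813e+03	2.571659e+01	2.240981e+00
3.020237e+03	2.567827e+01	2.109150e+00
3.130548e+03	2.563933e+01	1.983733e+00
3.244888e+03	2.559664e+01	1.865502e+00
3.363405e+03	2.555162e+01	1.754062e+00
3.486250e+03	2.550893e+01	1.648693e+00
3.613582e+03	2.545990e+01	1.549373e+00
3.745564e+03	2.540914e+01	1.455841e+00
3.882368e+03	2.535657e+01	1.367772e+00
4.024167e+03	2.530204e+01	1.284859e+00
4.171146e+03	2.524532e+01	1.206813e+00
4.323493e+03	2.518606e+01	1.133358e+00
4.481405e+03	2.512380e+01	1.064234e+00
4.645084e+03	2.505790e+01	9.991944e-01
4.814741e+03	2.498755e+01	9.380065e-01
4.990595e+03	2.491161e+01	8.804497e-01
5.172871e+03	2.482855e+01	8.263156e-01
5.361806e+03	2.473621e+01	7.754072e-01
5.557640e+03	2.463151e+01	7.275384e-01
5.760628e+03	2.450974e+01	6.825333e-01
5.971029e+03	2.436343e+01	6.402259e-01
6.189115e+03	2.417959e+01	6.004592e-01
6.415167e+03	2.393285e+01	5.630853e-01
6.649475e+03	2.356302e+01	5.279643e-01
6.892340e+03	2.285713e+01	4.949645e-01
7.144076e+03	2.095299e+01	3.915541e+00
7.405007e+03	2.354659e+01	3.647553e+00
7.675468e+03	2.427334e+01	3.442476e+00
7.955807e+03	2.474945e+01	3.255650e+00
8.246385e+03	2.508745e+01	3.076391e+00
8.547576e+03	2.534385e+01	2.904564e+00
8.859768e+03	2.554537e+01	2.740029e+00
9.183363e+03	2.570516e+01	2.582343e+00
9.518776e+03	2.583308e+01	2.433270e+00
9.866441e+03	2.593881e+01	2.292157e+00
1.022680e+04	2.602565e+01	2.158538e+00
1.060033e+04	2.609709e+01	2.032057e+00
1.098749e+04	2.615578e+01	1.912373e+00
1.138880e+04	2.620380e+01	1.799158e+00
1.180477e+04	2.624283e+01	1.692098e+00
1.223592e+04	2.627424e+01	1.590893e+00
1.268283e+04	2.629913e+01	1.495254e+00
1.314606e+04	2.631844e+01	1.404907e+00
1.362620e+04	2.633363e+01	1.319571e+00
1.412389e+04	2.634396e+01	1.238998e+00
1.463975e+04	2.635408e+01	1.162446e+00
1.517445e+04	2.635743e+01	1.090214e+00
1.572869e+04	2.635816e+01	1.022204e+00
1.630316e+04	2.635728e+01	9.581628e-01
1.689862e+04	2.635382e+01	8.978929e-01
1.751582e+04	2.634876e+01	8.411971e-01
1.815557e+04	2.634237e+01	7.878775e-01
1.881869e+04	2.633487e+01	7.377461e-01
1.950602e+04	2.632645e+01	6.906249e-01
2.021846e+04	2.631728e+01	6.463449e-01
2.095692e+04	2.630751e+01	6.047459e-01
2.172235e+04	2.629728e+01	5.656760e-01
2.251574e+04	2.628668e+01	5.289914e-01
2.333811e+04	2.627583e+01	4.945557e-01
2.419051e+04	2.626480e+01	4.622397e-01
2.507404e+04	2.625368e+01	4.319213e-01
2.598985e+04	2.624252e+01	4.034846e-01
2.693910e+04	2.623139e+01	3.767872e-01
2.792303e+04	2.622031e+01	3.516869e-01
2.894289e+04	2.620933e+01	3.281969e-01
3.000000e+04	2.619849e+01	3.062179e-01
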