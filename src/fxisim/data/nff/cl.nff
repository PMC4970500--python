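# Cl  Z=17  E(eV) f1 f2  (Cromer-Liberman, f1 = Z + f')
1.000000e+02	5.296751e+00	1.260323e+00
1.036524e+02	5.253761e+00	1.256609e+00
1.074382e+02	5.201749e+00	1.251644e+00
1.113623e+02	5.139345e+00	1.245441e+00
1.154297e+02	5.064923e+00	1.238016e+00
1.196456e+02	4.976532e+00	1.229390e+00
1.240156e+02	4.871800e+00	1.219587e+00
1.285451e+02	4.981197e+00	1.206288e+00
1.332401e+02	4.827393e+00	1.182058e+00
1.381066e+02	4.645445e+00	1.157605e+00
1.431508e+02	4.429357e+00	1.132967e+00
1.483792e+02	4.171078e+00	1.108179e+00
1.537987e+02	3.859557e+00	1.083276e+00
1.594160e+02	3.479139e+00	1.058293e+00
1.652385e+02	3.006792e+00	1.033263e+00
1.712737e+02	2.406994e+00	1.008220e+00
1.775293e+02	1.621619e+00	9.831950e-01
1.840134e+02	5.479079e-01	9.582199e-01
1.907343e+02	-1.015946e+00	9.333247e-01
1.977007e+02	-3.531600e+00	9.085386e-01
2.049215e+02	-4.455087e+00	1.511250e+01
2.124061e+02	5.960001e-01	1.462079e+01
2.201640e+02	3.199159e+00	1.413266e+01
2.282053e+02	4.969759e+00	1.364886e+01
2.365403e+02	6.305935e+00	1.317006e+01
2.451797e+02	7.350979e+00	1.269693e+01
2.541346e+02	8.168898e+00	1.223008e+01
2.634167e+02	8.771715e+00	1.177008e+01
2.730377e+02	8.956178e+00	1.263061e+01
2.830101e+02	1.022497e+01	1.219147e+01
2.933468e+02	1.104099e+01	1.175912e+01
3.040610e+02	1.170795e+01	1.133395e+01
3.151666e+02	1.228158e+01	1.091634e+01
3.266777e+02	1.278539e+01	1.050662e+01
3.386093e+02	1.329130e+01	1.010438e+01
3.509767e+02	1.371461e+01	9.698064e+00
3.637958e+02	1.406514e+01	9.301976e+00
3.770831e+02	1.437859e+01	8.917052e+00
3.908557e+02	1.465927e+01	8.543253e+00
4.051313e+02	1.491073e+01	8.180523e+00
4.199283e+02	1.513594e+01	7.828786e+00
4.352658e+02	1.533747e+01	7.487952e+00
4.511635e+02	1.551751e+01	7.157913e+00
4.676418e+02	1.571392e+01	6.834266e+00
4.847219e+02	1.585417e+01	6.519666e+00
5.024259e+02	1.597754e+01	6.216253e+00
5.207766e+02	1.608553e+01	5.923851e+00
5.397974e+02	1.617951e+01	5.642270e+00
5.595130e+02	1.626070e+01	5.371308e+00
5.799487e+02	1.633022e+01	5.110754e+00
6.011308e+02	1.638909e+01	4.860387e+00
6.230865e+02	1.643822e+01	4.619979e+00
6.458441e+02	1.647847e+01	4.389293e+00
6.694330e+02	1.651061e+01	4.168087e+00
6.938833e+02	1.653535e+01	3.956116e+00
7.192268e+02	1.655333e+01	3.753129e+00
7.454958e+02	1.656516e+01	3.558871e+00
7.727244e+02	1.657139e+01	3.373089e+00
8.009474e+02	1.658149e+01	3.195495e+00
8.302012e+02	1.657974e+01	3.024905e+00
8.605235e+02	1.656934e+01	2.862453e+00
8.919533e+02	1.655534e+01	2.707882e+00
9.245310e+02	1.653810e+01	2.560863e+00
9.582986e+02	1.651795e+01	2.421073e+00
9.932996e+02	1.649514e+01	2.288203e+00
1.029579e+03	1.647040e+01	2.160989e+00
1.067183e+03	1.644302e+01	2.040186e+00
1.106161e+03	1.641754e+01	1.925455e+00
1.146563e+03	1.638538e+01	1.816663e+00
1.188440e+03	1.635134e+01	1.713675e+00
1.231846e+03	1.631554e+01	1.616204e+00
1.276838e+03	1.627810e+01	1.523979e+00
1.323474e+03	1.623904e+01	1.436737e+00
1.371812e+03	1.619837e+01	1.354228e+00
1.421916e+03	1.615604e+01	1.276215e+00
1.473850e+03	1.611195e+01	1.202468e+00
1.527681e+03	1.606592e+01	1.132770e+00
1.583479e+03	1.601776e+01	1.066912e+00
1.641314e+03	1.596715e+01	1.004697e+00
1.701261e+03	1.591370e+01	9.459346e-01
1.763398e+03	1.585690e+01	8.904450e-01
1.827804e+03	1.579608e+01	8.380562e-01
1.894563e+03	1.573037e+01	7.886048e-01
1.963760e+03	1.565860e+01	7.419350e-01
2.035485e+03	1.557921e+01	6.978988e-01
2.109829e+03	1.549002e+01	6.563554e-01
2.186888e+03	1.538793e+01	6.171708e-01
2.266762e+03	1.526831e+01	5.802179e-01
2.349554e+03	1.512389e+01	5.453759e-01
2.435369e+03	1.494233e+01	5.125300e-01
2.524318e+03	1.470035e+01	4.815714e-01
2.616517e+03	1.434584e+01	4.523967e-01
2.712082e+03	1.371756e+01	4.249079e-01
2.811139e+03	1.119848e+01	3.990121e-01
2.913813e+03	1.386852e+01	3.919757e+00
3.020237e+03	1.488544e+01	3.705666e+00
3.130548e+03	1.545823e+01	3.502683e+00
3.244888e+03	1.585576e+01	3.309731e+00
3.363405e+03	1.615383e+01	3.126387e+00
3.486250e+03	1.638690e+01	2.952234e+00
3.613582e+03	1.657380e+01	2.786868e+00
3.745564e+03	1.672440e+01	2.630248e+00
3.882368e+03	1.685161e+01	2.481708e+00
4.024167e+03	1.695564e+01	2.340688e+00
4.171146e+03	1.704218e+01	2.206872e+00
4.323493e+03	1.711420e+01	2.079941e+00
4.481405e+03	1.717404e+01	1.959588e+00
4.645084e+03	1.722358e+01	1.845517e+00
4.814741e+03	1.726435e+01	1.737441e+00
4.990595e+03	1.729758e+01	1.635087e+00
5.172871e+03	1.732545e+01	1.538157e+00
5.361806e+03	1.734649e+01	1.446412e+00
5.557640e+03	1.736270e+01	1.359637e+00
5.760628e+03	1.737774e+01	1.277259e+00
5.971029e+03	1.738571e+01	1.199259e+00
6.189115e+03	1.739053e+01	1.125688e+00
6.415167e+03	1.739265e+01	1.056319e+00
6.649475e+03	1.739245e+01	9.909301e-01
6.892340e+03	1.739027e+01	9.293129e-01
7.144076e+03	1.738640e+01	8.712679e-01
7.405007e+03	1.738109e+01	8.166049e-01
7.675468e+03	1.737458e+01	7.651429e-01
7.955807e+03	1.736709e+01	7.167096e-01
8.246385e+03	1.735871e+01	6.711405e-01
8.547576e+03	1.734965e+01	6.282806e-01
8.859768e+03	1.734003e+01	5.879817e-01
9.183363e+03	1.732998e+01	5.499270e-01
9.518776e+03	1.731955e+01	5.141910e-01
9.866441e+03	1.730886e+01	4.806662e-01
1.022680e+04	1.729800e+01	4.492234e-01
1.060033e+04	1.728704e+01	4.197402e-01
1.098749e+04	1.727607e+01	3.921009e-01
1.138880e+04	1.726512e+01	3.661964e-01
1.180477e+04	1.725426e+01	3.419237e-01
1.223592e+04	1.724533e+01	3.191829e-01
1.268283e+04	1.723452e+01	2.977168e-01
1.314606e+04	1.722394e+01	2.776445e-01
1.362620e+04	1.721359e+01	2.588791e-01
1.412389e+04	1.720347e+01	2.413385e-01
1.463975e+04	1.719361e+01	2.249458e-01
1.517445e+04	1.718402e+01	2.096287e-01
1.572869e+04	1.717471e+01	1.953192e-01
1.630316e+04	1.716569e+01	1.819535e-01
1.689862e+04	1.715696e+01	1.694717e-01
1.751582e+04	1.714852e+01	1.578174e-01
1.815557e+04	1.714038e+01	1.469377e-01
1.881869e+04	1.713254e+01	1.367832e-01
1.950602e+04	1.712499e+01	1.273071e-01
2.021846e+04	1.711773e+01	1.184659e-01
2.095692e+04	1.711076e+01	1.102184e-01
2.172235e+04	1.710407e+01	1.025264e-01
2.251574e+04	1.709766e+01	9.535362e-02
2.333811e+04	1.709151e+01	8.866637e-02
2.419051e+04	1.708563e+01	8.243293e-02
2.507404e+04	1.708000e+01	7.662358e-02
2.598985e+04	1.707462e+01	7.121050e-02
2.693910e+04	1.706948e+01	6.615764e-02
2.792303e+04	1.706456e+01	6.142598e-02
2.894289e+04	1.705987e+01	5.702514e-02
3.000000e+04	1.705539e+01	5.293252e-02
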