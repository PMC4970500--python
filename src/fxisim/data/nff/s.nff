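# S  Z=16  E(eV) f1 f2  (Cromer-Liberman, f1 = Z + f')
1.000000e+02	4.070300e+00	8.201905e-01
1.036524e+02	3.953808e+00	8.219211e-01
1.074382e+02	3.818679e+00	8.227651e-01
1.113623e+02	3.661150e+00	8.227085e-01
1.154297e+02	3.476383e+00	8.217412e-01
1.196456e+02	3.258021e+00	8.198565e-01
1.240156e+02	2.997507e+00	8.170521e-01
1.285451e+02	2.682975e+00	8.133292e-01
1.332401e+02	2.297393e+00	8.086932e-01
1.381066e+02	1.815253e+00	8.031531e-01
1.431508e+02	1.196293e+00	7.967223e-01
1.483792e+02	6.008491e-01	7.838136e-01
1.537987e+02	-5.608398e-01	7.639583e-01
1.594160e+02	-2.315078e+00	7.442049e-01
1.652385e+02	-1.325925e+01	1.335548e+01
1.712737e+02	-2.071088e+00	1.309370e+01
1.775293e+02	9.091423e-01	1.282059e+01
1.840134e+02	2.777465e+00	1.253708e+01
1.907343e+02	4.157007e+00	1.224409e+01
1.977007e+02	5.248654e+00	1.194260e+01
2.049215e+02	6.139196e+00	1.163357e+01
2.124061e+02	6.867461e+00	1.131797e+01
2.201640e+02	7.440429e+00	1.099679e+01
2.282053e+02	7.821640e+00	1.067098e+01
2.365403e+02	8.545620e+00	1.157192e+01
2.451797e+02	9.401396e+00	1.124805e+01
2.541346e+02	1.008060e+01	1.092089e+01
2.634167e+02	1.066753e+01	1.059132e+01
2.730377e+02	1.118941e+01	1.026020e+01
2.830101e+02	1.196203e+01	9.904060e+00
2.933468e+02	1.236350e+01	9.524391e+00
3.040610e+02	1.272288e+01	9.153971e+00
3.151666e+02	1.304562e+01	8.792863e+00
3.266777e+02	1.333606e+01	8.441110e+00
3.386093e+02	1.359894e+01	8.098698e+00
3.509767e+02	1.383463e+01	7.765641e+00
3.637958e+02	1.404694e+01	7.441959e+00
3.770831e+02	1.423801e+01	7.127621e+00
3.908557e+02	1.445354e+01	6.820593e+00
4.051313e+02	1.460525e+01	6.517435e+00
4.199283e+02	1.473993e+01	6.224304e+00
4.352658e+02	1.485904e+01	5.941099e+00
4.511635e+02	1.496394e+01	5.667701e+00
4.676418e+02	1.505582e+01	5.403980e+00
4.847219e+02	1.513577e+01	5.149789e+00
5.024259e+02	1.520479e+01	4.904971e+00
5.207766e+02	1.526380e+01	4.669360e+00
5.397974e+02	1.531362e+01	4.442776e+00
5.595130e+02	1.535502e+01	4.225034e+00
5.799487e+02	1.538870e+01	4.015939e+00
6.011308e+02	1.541531e+01	3.815291e+00
6.230865e+02	1.543545e+01	3.622884e+00
6.458441e+02	1.544966e+01	3.438505e+00
6.694330e+02	1.548651e+01	3.260751e+00
6.938833e+02	1.548631e+01	3.089593e+00
7.192268e+02	1.548182e+01	2.926525e+00
7.454958e+02	1.547347e+01	2.771221e+00
7.727244e+02	1.546164e+01	2.623362e+00
8.009474e+02	1.544667e+01	2.482639e+00
8.302012e+02	1.542885e+01	2.348754e+00
8.605235e+02	1.540845e+01	2.221416e+00
8.919533e+02	1.538568e+01	2.100345e+00
9.245310e+02	1.536180e+01	1.985248e+00
9.582986e+02	1.533437e+01	1.875866e+00
9.932996e+02	1.530508e+01	1.772059e+00
1.029579e+03	1.527559e+01	1.672445e+00
1.067183e+03	1.524375e+01	1.577873e+00
1.106161e+03	1.520971e+01	1.488364e+00
1.146563e+03	1.517374e+01	1.403667e+00
1.188440e+03	1.513594e+01	1.323542e+00
1.231846e+03	1.509632e+01	1.247759e+00
1.276838e+03	1.505483e+01	1.176098e+00
1.323474e+03	1.501134e+01	1.108350e+00
1.371812e+03	1.496566e+01	1.044313e+00
1.421916e+03	1.491753e+01	9.837978e-01
1.473850e+03	1.486656e+01	9.266214e-01
1.527681e+03	1.481230e+01	8.726104e-01
1.583479e+03	1.475413e+01	8.215992e-01
1.641314e+03	1.469121e+01	7.734305e-01
1.701261e+03	1.462249e+01	7.279543e-01
1.763398e+03	1.454652e+01	6.850279e-01
1.827804e+03	1.446130e+01	6.445158e-01
1.894563e+03	1.436403e+01	6.062889e-01
1.963760e+03	1.425058e+01	5.702247e-01
2.035485e+03	1.411457e+01	5.362067e-01
2.109829e+03	1.394547e+01	5.041245e-01
2.186888e+03	1.372413e+01	4.738729e-01
2.266762e+03	1.341022e+01	4.453524e-01
2.349554e+03	1.289399e+01	4.184685e-01
2.435369e+03	1.159884e+01	3.931316e-01
2.524318e+03	1.223314e+01	4.001381e+00
2.616517e+03	1.359541e+01	3.804971e+00
2.712082e+03	1.426664e+01	3.592905e+00
2.811139e+03	1.471186e+01	3.392985e+00
2.913813e+03	1.503831e+01	3.204500e+00
3.020237e+03	1.529063e+01	3.027006e+00
3.130548e+03	1.549523e+01	2.859683e+00
3.244888e+03	1.566109e+01	2.700365e+00
3.363405e+03	1.579657e+01	2.548675e+00
3.486250e+03	1.590889e+01	2.404635e+00
3.613582e+03	1.600266e+01	2.267908e+00
3.745564e+03	1.608061e+01	2.138175e+00
3.882368e+03	1.614558e+01	2.015127e+00
4.024167e+03	1.619957e+01	1.898465e+00
4.171146e+03	1.624421e+01	1.787900e+00
4.323493e+03	1.628234e+01	1.683146e+00
4.481405e+03	1.631197e+01	1.583882e+00
4.645084e+03	1.633566e+01	1.489929e+00
4.814741e+03	1.635423e+01	1.401035e+00
4.990595e+03	1.637248e+01	1.316748e+00
5.172871e+03	1.638226e+01	1.236570e+00
5.361806e+03	1.638865e+01	1.160935e+00
5.557640e+03	1.639214e+01	1.089609e+00
5.760628e+03	1.639313e+01	1.022365e+00
5.971029e+03	1.639199e+01	9.589905e-01
6.189115e+03	1.638902e+01	8.992804e-01
6.415167e+03	1.638450e+01	8.430403e-01
6.649475e+03	1.637866e+01	7.900847e-01
6.892340e+03	1.637172e+01	7.402372e-01
7.144076e+03	1.636385e+01	6.933299e-01
7.405007e+03	1.635523e+01	6.492030e-01
7.675468e+03	1.634599e+01	6.077046e-01
7.955807e+03	1.633626e+01	5.686902e-01
8.246385e+03	1.632616e+01	5.320221e-01
8.547576e+03	1.631576e+01	4.975706e-01
8.859768e+03	1.630516e+01	4.652119e-01
9.183363e+03	1.629438e+01	4.347319e-01
9.518776e+03	1.628352e+01	4.061422e-01
9.866441e+03	1.627265e+01	3.793467e-01
1.022680e+04	1.626182e+01	3.542385e-01
1.060033e+04	1.625109e+01	3.307168e-01
1.098749e+04	1.624215e+01	3.085596e-01
1.138880e+04	1.623155e+01	2.877836e-01
1.180477e+04	1.622115e+01	2.683576e-01
1.223592e+04	1.621097e+01	2.501974e-01
1.268283e+04	1.620103e+01	2.332235e-01
1.314606e+04	1.619136e+01	2.173614e-01
1.362620e+04	1.618195e+01	2.025410e-01
1.412389e+04	1.617282e+01	1.886965e-01
1.463975e+04	1.616398e+01	1.757660e-01
1.517445e+04	1.615544e+01	1.636915e-01
1.572869e+04	1.614718e+01	1.524183e-01
1.630316e+04	1.613922e+01	1.418953e-01
1.689862e+04	1.613155e+01	1.320744e-01
1.751582e+04	1.612417e+01	1.229105e-01
1.815557e+04	1.611708e+01	1.143612e-01
1.881869e+04	1.611026e+01	1.063869e-01
1.950602e+04	1.610373e+01	9.895018e-02
2.021846e+04	1.609746e+01	9.201621e-02
2.095692e+04	1.609146e+01	8.555221e-02
2.172235e+04	1.608572e+01	7.952747e-02
2.251574e+04	1.608023e+01	7.391321e-02
2.333811e+04	1.607498e+01	6.868246e-02
2.419051e+04	1.606997e+01	6.380995e-02
2.507404e+04	1.606519e+01	5.927202e-02
2.598985e+04	1.606063e+01	5.504649e-02
2.693910e+04	1.605627e+01	5.110514e-02
2.792303e+04	1.605211e+01	4.741799e-02
2.894289e+04	1.604815e+01	4.399139e-02
3.000000e+04	1.604438e+01	4.080733e-02
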