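# Ca  Z=20  E(eV) f1 f2  (Cromer-Liberman, f1 = Z + f')
1.000000e+02	8.121319e+00	2.254745e+00
1.036524e+02	8.500760e+00	2.275686e+00
1.074382e+02	8.557454e+00	2.280309e+00
1.113623e+02	8.612197e+00	2.282738e+00
1.154297e+02	8.664734e+00	2.282967e+00
1.196456e+02	8.714778e+00	2.280996e+00
1.240156e+02	8.762015e+00	2.276831e+00
1.285451e+02	8.806101e+00	2.270485e+00
1.332401e+02	8.846660e+00	2.261979e+00
1.381066e+02	8.883276e+00	2.251337e+00
1.431508e+02	8.915495e+00	2.238590e+00
1.483792e+02	8.942812e+00	2.223777e+00
1.537987e+02	8.964665e+00	2.206941e+00
1.594160e+02	8.980425e+00	2.188131e+00
1.652385e+02	8.989383e+00	2.167402e+00
1.712737e+02	8.990735e+00	2.144811e+00
1.775293e+02	9.016352e+00	2.119026e+00
1.840134e+02	8.998543e+00	2.089832e+00
1.907343e+02	8.969687e+00	2.059203e+00
1.977007e+02	8.928332e+00	2.027215e+00
2.049215e+02	8.872738e+00	1.993946e+00
2.124061e+02	8.800788e+00	1.959476e+00
2.201640e+02	8.709877e+00	1.923888e+00
2.282053e+02	8.596749e+00	1.887266e+00
2.365403e+02	8.457265e+00	1.849696e+00
2.451797e+02	8.286061e+00	1.811265e+00
2.541346e+02	8.076031e+00	1.772061e+00
2.634167e+02	7.817523e+00	1.732172e+00
2.730377e+02	7.497020e+00	1.691685e+00
2.830101e+02	7.094904e+00	1.650689e+00
2.933468e+02	6.581426e+00	1.609270e+00
3.040610e+02	5.908938e+00	1.567515e+00
3.151666e+02	4.995537e+00	1.525508e+00
3.266777e+02	3.686496e+00	1.483333e+00
3.386093e+02	1.647621e+00	1.441071e+00
3.509767e+02	-4.942873e+00	1.565361e+01
3.637958e+02	3.688906e+00	1.502695e+01
3.770831e+02	6.753526e+00	1.441359e+01
3.908557e+02	8.688351e+00	1.381398e+01
4.051313e+02	1.006046e+01	1.322851e+01
4.199283e+02	1.105121e+01	1.265752e+01
4.352658e+02	1.169538e+01	1.210131e+01
4.511635e+02	1.265543e+01	1.310787e+01
4.676418e+02	1.377828e+01	1.257037e+01
4.847219e+02	1.468234e+01	1.204547e+01
5.024259e+02	1.537983e+01	1.153342e+01
5.207766e+02	1.597386e+01	1.103605e+01
5.397974e+02	1.648756e+01	1.055338e+01
5.595130e+02	1.693564e+01	1.008541e+01
5.799487e+02	1.732848e+01	9.632094e+00
6.011308e+02	1.771922e+01	9.188172e+00
6.230865e+02	1.801758e+01	8.757362e+00
6.458441e+02	1.827929e+01	8.342672e+00
6.694330e+02	1.850874e+01	7.943736e+00
6.938833e+02	1.870960e+01	7.560183e+00
7.192268e+02	1.888501e+01	7.191636e+00
7.454958e+02	1.904624e+01	6.837386e+00
7.727244e+02	1.917731e+01	6.496415e+00
8.009474e+02	1.928991e+01	6.169717e+00
8.302012e+02	1.938639e+01	5.856874e+00
8.605235e+02	1.946747e+01	5.557469e+00
8.919533e+02	1.953517e+01	5.271109e+00
9.245310e+02	1.959083e+01	4.997381e+00
9.582986e+02	1.963564e+01	4.735875e+00
9.932996e+02	1.967068e+01	4.486183e+00
1.029579e+03	1.969604e+01	4.245657e+00
1.067183e+03	1.971297e+01	4.016317e+00
1.106161e+03	1.972258e+01	3.798267e+00
1.146563e+03	1.972569e+01	3.591029e+00
1.188440e+03	1.972304e+01	3.394140e+00
1.231846e+03	1.971527e+01	3.207152e+00
1.276838e+03	1.970295e+01	3.029629e+00
1.323474e+03	1.968659e+01	2.861153e+00
1.371812e+03	1.966662e+01	2.701317e+00
1.421916e+03	1.965420e+01	2.549079e+00
1.473850e+03	1.962696e+01	2.404499e+00
1.527681e+03	1.959719e+01	2.267637e+00
1.583479e+03	1.956517e+01	2.138113e+00
1.641314e+03	1.953109e+01	2.015562e+00
1.701261e+03	1.949513e+01	1.899637e+00
1.763398e+03	1.946126e+01	1.789932e+00
1.827804e+03	1.942153e+01	1.685943e+00
1.894563e+03	1.938019e+01	1.587697e+00
1.963760e+03	1.933725e+01	1.494900e+00
2.035485e+03	1.929269e+01	1.407269e+00
2.109829e+03	1.924644e+01	1.324534e+00
2.186888e+03	1.919834e+01	1.246438e+00
2.266762e+03	1.914820e+01	1.172737e+00
2.349554e+03	1.909575e+01	1.103197e+00
2.435369e+03	1.904062e+01	1.037597e+00
2.524318e+03	1.898233e+01	9.757265e-01
2.616517e+03	1.892023e+01	9.173839e-01
2.712082e+03	1.885349e+01	8.623787e-01
2.811139e+03	1.878101e+01	8.105299e-01
2.913813e+03	1.870126e+01	7.616652e-01
3.020237e+03	1.861214e+01	7.155293e-01
3.130548e+03	1.851062e+01	6.717171e-01
3.244888e+03	1.839222e+01	6.305108e-01
3.363405e+03	1.824993e+01	5.917598e-01
3.486250e+03	1.807178e+01	5.553218e-01
3.613582e+03	1.783515e+01	5.210625e-01
3.745564e+03	1.748913e+01	4.888550e-01
3.882368e+03	1.687455e+01	4.585797e-01
4.024167e+03	1.427592e+01	4.301237e-01
4.171146e+03	1.708429e+01	3.822297e+00
4.323493e+03	1.800769e+01	3.601060e+00
4.481405e+03	1.855596e+01	3.404121e+00
4.645084e+03	1.893587e+01	3.216694e+00
4.814741e+03	1.922060e+01	3.038395e+00
4.990595e+03	1.944313e+01	2.868851e+00
5.172871e+03	1.962146e+01	2.707701e+00
5.361806e+03	1.976739e+01	2.554432e+00
5.557640e+03	1.988658e+01	2.408815e+00
5.760628e+03	1.998508e+01	2.270640e+00
5.971029e+03	2.006670e+01	2.139580e+00
6.189115e+03	2.013433e+01	2.015319e+00
6.415167e+03	2.019024e+01	1.897553e+00
6.649475e+03	2.023665e+01	1.785977e+00
6.892340e+03	2.027415e+01	1.680314e+00
7.144076e+03	2.030444e+01	1.580302e+00
7.405007e+03	2.032853e+01	1.485678e+00
7.675468e+03	2.034728e+01	1.396187e+00
7.955807e+03	2.036143e+01	1.311586e+00
8.246385e+03	2.037220e+01	1.231583e+00
8.547576e+03	2.037860e+01	1.156043e+00
8.859768e+03	2.038205e+01	1.084802e+00
9.183363e+03	2.038397e+01	1.017083e+00
9.518776e+03	2.038312e+01	9.532805e-01
9.866441e+03	2.038007e+01	8.932636e-01
1.022680e+04	2.037527e+01	8.368214e-01
1.060033e+04	2.036905e+01	7.837541e-01
1.098749e+04	2.036167e+01	7.338723e-01
1.138880e+04	2.035335e+01	6.869965e-01
1.180477e+04	2.034431e+01	6.429559e-01
1.223592e+04	2.033462e+01	6.015899e-01
1.268283e+04	2.032446e+01	5.627461e-01
1.314606e+04	2.031394e+01	5.262800e-01
1.362620e+04	2.030316e+01	4.920547e-01
1.412389e+04	2.029222e+01	4.599407e-01
1.463975e+04	2.028119e+01	4.298155e-01
1.517445e+04	2.027012e+01	4.015630e-01
1.572869e+04	2.025908e+01	3.750737e-01
1.630316e+04	2.024812e+01	3.502440e-01
1.689862e+04	2.023727e+01	3.269758e-01
1.751582e+04	2.022765e+01	3.051732e-01
1.815557e+04	2.021702e+01	2.846522e-01
1.881869e+04	2.020656e+01	2.654621e-01
1.950602e+04	2.019634e+01	2.475198e-01
2.021846e+04	2.018636e+01	2.307476e-01
2.095692e+04	2.017666e+01	2.150720e-01
2.172235e+04	2.016724e+01	2.004240e-01
2.251574e+04	2.015810e+01	1.867387e-01
2.333811e+04	2.014926e+01	1.739554e-01
2.419051e+04	2.014071e+01	1.620168e-01
2.507404e+04	2.013246e+01	1.508692e-01
2.598985e+04	2.012451e+01	1.404622e-01
2.693910e+04	2.011687e+01	1.307029e-01
2.792303e+04	2.010954e+01	1.214774e-01
2.894289e+04	2.010248e+01	1.128923e-01
3.000000e+04	2.009567e+01	1.049037e-01
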