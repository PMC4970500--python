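# K  Z=19  E(eV) f1 f2  (Cromer-Liberman, f1 = Z + f')
1.000000e+02	7.647207e+00	1.739498e+00
1.036524e+02	7.662195e+00	1.753316e+00
1.074382e+02	7.676438e+00	1.765220e+00
1.113623e+02	7.689457e+00	1.775168e+00
1.154297e+02	7.700745e+00	1.783127e+00
1.196456e+02	7.709760e+00	1.789071e+00
1.240156e+02	7.715921e+00	1.792977e+00
1.285451e+02	7.718597e+00	1.794835e+00
1.332401e+02	7.717095e+00	1.794637e+00
1.381066e+02	7.759272e+00	1.789934e+00
1.431508e+02	7.745712e+00	1.781052e+00
1.483792e+02	7.725085e+00	1.770425e+00
1.537987e+02	7.696328e+00	1.758080e+00
1.594160e+02	7.658216e+00	1.744049e+00
1.652385e+02	7.609309e+00	1.728369e+00
1.712737e+02	7.547905e+00	1.711082e+00
1.775293e+02	7.471962e+00	1.692236e+00
1.840134e+02	7.378994e+00	1.671884e+00
1.907343e+02	7.265930e+00	1.650083e+00
1.977007e+02	7.128912e+00	1.626895e+00
2.049215e+02	6.963001e+00	1.602385e+00
2.124061e+02	6.761731e+00	1.576622e+00
2.201640e+02	6.516432e+00	1.549680e+00
2.282053e+02	6.215138e+00	1.521632e+00
2.365403e+02	5.840765e+00	1.492558e+00
2.451797e+02	5.367897e+00	1.462538e+00
2.541346e+02	4.756769e+00	1.431652e+00
2.634167e+02	3.941047e+00	1.399984e+00
2.730377e+02	2.800343e+00	1.367617e+00
2.830101e+02	1.089201e+00	1.334637e+00
2.933468e+02	-1.787445e+00	1.301126e+00
3.040610e+02	3.277215e-01	1.509710e+01
3.151666e+02	4.220334e+00	1.455227e+01
3.266777e+02	6.469665e+00	1.401378e+01
3.386093e+02	8.176148e+00	1.347977e+01
3.509767e+02	9.331677e+00	1.294958e+01
3.637958e+02	1.017640e+01	1.242885e+01
3.770831e+02	1.070124e+01	1.191817e+01
3.908557e+02	1.176525e+01	1.294985e+01
4.051313e+02	1.279588e+01	1.244866e+01
4.199283e+02	1.359883e+01	1.195764e+01
4.352658e+02	1.427175e+01	1.147718e+01
4.511635e+02	1.485131e+01	1.100763e+01
4.676418e+02	1.535734e+01	1.054932e+01
4.847219e+02	1.580259e+01	1.010249e+01
5.024259e+02	1.630584e+01	9.662209e+00
5.207766e+02	1.664375e+01	9.221685e+00
5.397974e+02	1.694101e+01	8.796854e+00
5.595130e+02	1.720265e+01	8.387426e+00
5.799487e+02	1.743282e+01	7.993098e+00
6.011308e+02	1.763503e+01	7.613556e+00
6.230865e+02	1.781228e+01	7.248477e+00
6.458441e+02	1.797639e+01	6.896962e+00
6.694330e+02	1.811024e+01	6.558499e+00
6.938833e+02	1.822587e+01	6.233781e+00
7.192268e+02	1.832510e+01	5.922444e+00
7.454958e+02	1.840953e+01	5.624122e+00
7.727244e+02	1.848062e+01	5.338443e+00
8.009474e+02	1.853967e+01	5.065037e+00
8.302012e+02	1.858783e+01	4.803530e+00
8.605235e+02	1.862617e+01	4.553551e+00
8.919533e+02	1.865563e+01	4.314730e+00
9.245310e+02	1.867708e+01	4.086697e+00
9.582986e+02	1.869130e+01	3.869087e+00
9.932996e+02	1.869899e+01	3.661539e+00
1.029579e+03	1.869929e+01	3.462432e+00
1.067183e+03	1.869392e+01	3.272931e+00
1.106161e+03	1.868382e+01	3.092958e+00
1.146563e+03	1.866952e+01	2.922095e+00
1.188440e+03	1.866462e+01	2.759626e+00
1.231846e+03	1.864193e+01	2.604650e+00
1.276838e+03	1.861633e+01	2.457851e+00
1.323474e+03	1.858811e+01	2.318834e+00
1.371812e+03	1.855757e+01	2.187219e+00
1.421916e+03	1.852492e+01	2.062642e+00
1.473850e+03	1.849036e+01	1.944757e+00
1.527681e+03	1.845839e+01	1.833077e+00
1.583479e+03	1.842004e+01	1.727211e+00
1.641314e+03	1.838010e+01	1.627151e+00
1.701261e+03	1.833861e+01	1.532601e+00
1.763398e+03	1.829556e+01	1.443277e+00
1.827804e+03	1.825091e+01	1.358910e+00
1.894563e+03	1.820454e+01	1.279242e+00
1.963760e+03	1.815632e+01	1.204027e+00
2.035485e+03	1.810601e+01	1.133031e+00
2.109829e+03	1.805333e+01	1.066031e+00
2.186888e+03	1.799786e+01	1.002816e+00
2.266762e+03	1.793911e+01	9.431827e-01
2.349554e+03	1.787639e+01	8.869394e-01
2.435369e+03	1.780882e+01	8.339034e-01
2.524318e+03	1.773521e+01	7.839013e-01
2.616517e+03	1.765397e+01	7.367680e-01
2.712082e+03	1.756284e+01	6.923471e-01
2.811139e+03	1.745862e+01	6.504899e-01
2.913813e+03	1.733649e+01	6.110554e-01
3.020237e+03	1.718875e+01	5.738403e-01
3.130548e+03	1.700210e+01	5.385320e-01
3.244888e+03	1.675121e+01	5.053358e-01
3.363405e+03	1.637686e+01	4.741285e-01
3.486250e+03	1.567973e+01	4.447938e-01
3.613582e+03	1.243108e+01	4.055244e+00
3.745564e+03	1.620571e+01	3.821040e+00
3.882368e+03	1.706857e+01	3.609373e+00
4.024167e+03	1.759254e+01	3.411307e+00
4.171146e+03	1.796110e+01	3.222935e+00
4.323493e+03	1.823938e+01	3.043852e+00
4.481405e+03	1.845782e+01	2.873666e+00
4.645084e+03	1.863334e+01	2.712000e+00
4.814741e+03	1.877625e+01	2.558545e+00
4.990595e+03	1.889409e+01	2.412892e+00
5.172871e+03	1.899163e+01	2.274676e+00
5.361806e+03	1.907254e+01	2.143571e+00
5.557640e+03	1.914013e+01	2.019255e+00
5.760628e+03	1.919583e+01	1.901403e+00
5.971029e+03	1.924146e+01	1.789758e+00
6.189115e+03	1.927875e+01	1.684036e+00
6.415167e+03	1.930889e+01	1.583962e+00
6.649475e+03	1.933288e+01	1.489273e+00
6.892340e+03	1.935157e+01	1.399714e+00
7.144076e+03	1.936610e+01	1.315036e+00
7.405007e+03	1.937735e+01	1.234829e+00
7.675468e+03	1.938368e+01	1.159092e+00
7.955807e+03	1.938707e+01	1.087671e+00
8.246385e+03	1.938796e+01	1.020343e+00
8.547576e+03	1.938666e+01	9.568918e-01
8.859768e+03	1.938352e+01	8.971143e-01
9.183363e+03	1.937912e+01	8.404158e-01
9.518776e+03	1.937321e+01	7.870563e-01
9.866441e+03	1.936605e+01	7.369091e-01
1.022680e+04	1.935788e+01	6.897922e-01
1.060033e+04	1.934891e+01	6.455332e-01
1.098749e+04	1.933929e+01	6.039689e-01
1.138880e+04	1.932918e+01	5.649448e-01
1.180477e+04	1.931869e+01	5.283146e-01
1.223592e+04	1.930793e+01	4.939400e-01
1.268283e+04	1.929699e+01	4.616900e-01
1.314606e+04	1.928595e+01	4.314408e-01
1.362620e+04	1.927488e+01	4.030754e-01
1.412389e+04	1.926383e+01	3.764830e-01
1.463975e+04	1.925285e+01	3.515591e-01
1.517445e+04	1.924198e+01	3.282048e-01
1.572869e+04	1.923258e+01	3.063023e-01
1.630316e+04	1.922188e+01	2.856912e-01
1.689862e+04	1.921139e+01	2.664183e-01
1.751582e+04	1.920114e+01	2.484001e-01
1.815557e+04	1.919114e+01	2.315580e-01
1.881869e+04	1.918141e+01	2.158181e-01
1.950602e+04	1.917195e+01	2.011111e-01
2.021846e+04	1.916279e+01	1.873718e-01
2.095692e+04	1.915391e+01	1.745388e-01
2.172235e+04	1.914534e+01	1.625547e-01
2.251574e+04	1.913706e+01	1.513653e-01
2.333811e+04	1.912907e+01	1.409200e-01
2.419051e+04	1.912139e+01	1.311711e-01
2.507404e+04	1.911399e+01	1.220739e-01
2.598985e+04	1.910689e+01	1.135865e-01
2.693910e+04	1.910007e+01	1.056358e-01
2.792303e+04	1.909354e+01	9.813443e-02
2.894289e+04	1.908726e+01	9.115663e-02
3.000000e+04	1.908123e+01	8.466652e-02
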