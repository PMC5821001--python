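label,x,y,z
E1,9.199930,0.000000,0.035937
E2,-6.783328,-6.214084,0.107812
E3,0.804163,9.163025,0.179688
E4,5.595545,-7.298397,0.251562
E5,-9.053764,1.601483,0.323437
E6,7.755379,4.933338,0.395312
E7,-2.385278,-8.873116,0.467187
E8,-4.233059,8.150498,0.539062
E9,8.622681,-3.148989,0.610937
E10,-8.480525,-3.500637,0.682812
E11,3.886241,8.304672,0.754687
E12,2.742276,-8.742809,0.826562
E13,-7.921896,4.590901,0.898437
E14,8.935302,1.964401,0.970312
E15,-5.257131,-7.477728,1.042187
E16,-1.173598,9.056574,1.114062
E17,6.976078,-5.879446,1.185937
E18,-9.105829,-0.376555,1.257812
E19,6.452759,6.421357,1.329687
E20,-0.420001,-9.082908,1.401562
E21,-5.818436,6.972431,1.473437
E22,8.988295,-1.209362,1.545312
E23,-7.434308,-5.172598,1.617187
E24,1.984906,8.823107,1.689062
E25,4.489494,-7.834765,1.760937
E26,-8.589084,2.740152,1.832812
E27,8.170734,3.775086,1.904687
E28,-3.468823,-8.288575,1.976562
E29,-3.035596,8.439731,2.048437
E30,7.924511,-4.164901,2.120312
E31,-8.639882,-2.277445,2.192187
E32,4.822684,7.500382,2.264062
E33,1.507195,-8.769935,2.335938
E34,-7.020201,5.436838,2.407812
E35,8.829274,0.731487,2.479687
E36,-6.002444,-6.488466,2.551562
E37,0.043017,8.817921,2.623437
E38,5.910119,-6.515043,2.695312
E39,-8.736536,0.809700,2.767187
E40,6.970679,5.290497,2.839062
E41,-1.562050,-8.586410,2.910937
E42,-4.635285,7.365932,2.982812
E43,8.369452,-2.293720,3.054687
E44,-7.697952,-3.950462,3.126562
E45,2.998585,8.088169,3.198437
E46,3.242239,-7.964480,3.270312
E47,-7.745642,3.670805,3.342187
E48,8.163874,2.517010,3.414062
E49,-4.304870,-7.345498,3.485937
E50,-1.781282,8.295119,3.557812
E51,6.891870,-4.895661,3.629687
E52,-8.357838,-1.041621,3.701562
E53,5.438492,6.389364,3.773437
E54,0.304587,-8.352293,3.845312
E55,-5.843011,5.929154,3.917187
E56,8.279382,-0.423330,3.989062
E57,-6.363956,-5.258217,4.060937
E58,1.135769,8.140632,4.132812
E59,4.640718,-6.739758,4.204687
E60,-7.938180,1.826557,4.276562
E61,7.054003,3.996516,4.348437
E62,-2.489771,-7.674756,4.420312
E63,-3.331829,7.304736,4.492188
E64,7.353653,-3.119795,4.564062
E65,-7.490629,-2.653027,4.635937
E66,3.711369,6.978699,4.707812
E67,1.966575,-7.610990,4.779687
E68,-6.554218,4.259644,4.851562
E69,7.665769,1.278965,4.923437
E70,-4.760227,-6.084989,4.995312
E71,-0.596660,7.655561,5.067187
E72,5.576201,-5.209224,5.139062
E73,-7.581600,0.073973,5.210938
E74,5.603280,5.033403,5.282812
E75,-0.726722,-7.445750,5.354687
E76,-4.462453,5.939607,5.426562
E77,7.250487,-1.355591,5.498437
E78,-6.216020,-3.869458,5.570312
E79,1.954858,6.998875,5.642187
E80,3.260724,-6.430954,5.714062
E81,-6.694543,2.519131,5.785937
E82,6.583482,2.642688,5.857812
E83,-3.043399,-6.341650,5.929687
E84,-2.021863,6.673329,6.001562
E85,5.944849,-3.523085,6.073437
E86,-6.700876,-1.404776,6.145312
E87,3.954087,5.509244,6.217187
E88,0.797906,-6.667161,6.289062
E89,-5.040351,4.332821,6.360937
E90,6.573874,0.207626,6.432812
E91,-4.656254,-4.544044,6.504687
E92,0.359855,6.423343,6.576562
E93,4.026511,-4.921940,6.648437
E94,-6.218522,0.898546,6.720312
E95,5.128036,3.494200,6.792187
E96,-1.402729,-5.962969,6.864062
E97,-2.953769,5.273331,6.935937
E98,5.660820,-1.866999,7.007812
E99,-5.357246,-2.412040,7.079687
E100,2.286310,5.316760,7.151562
E101,1.875946,-5.379849,7.223437
E102,-4.935997,2.656002,7.295312
E103,5.341845,1.352495,7.367187
E104,-2.971825,-4.524224,7.439062
E105,-0.848733,5.244566,7.510937
E106,4.087590,-3.229948,7.582812
E107,-5.089949,-0.371729,7.654687
E108,3.426941,3.632673,7.726562
E109,-0.071431,-4.880499,7.798437
E110,-3.166457,3.559738,7.870312
E111,4.619237,-0.473608,7.942187
E112,-3.625553,-2.696325,8.014062
E113,0.827528,4.309618,8.085938
E114,2.230073,-3.621722,8.157812
E115,-3.955406,1.125615,8.229687
E116,3.545420,1.775966,8.301562
E117,-1.359653,-3.560462,8.373437
E118,-1.342865,3.393142,8.445312
E119,3.128367,-1.520144,8.517187
E120,-3.159662,-0.940500,8.589062
E121,1.594954,2.661632,8.660937
E122,0.580063,-2.835756,8.732812
E123,-2.159788,1.566140,8.804688
E124,2.402223,0.275611,8.876562
E125,-1.400749,-1.613496,8.948437
E126,-0.048296,1.808765,9.020312
E127,0.975909,-1.009816,9.092187
E128,-0.810875,0.049397,9.164062
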