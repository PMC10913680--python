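{"clr":[[0.631831592998,-1.7660636798,0.690672093021,-0.37976931868,0.746241944176,-0.37976931868,0.0256957894281,0.431160897536],[-1.21932241001,0.12441233669,0.0334405584845,0.454654023561,0.677797574875,0.284754986765,-0.177868535183,-0.177868535183],[0.773792092155,1.43708630957,0.50552810556,-0.113511102846,0.579636077714,-2.0594212519,-0.449983339467,-0.673126890781],[0.303165597832,0.236474223334,0.201382903522,-0.186382627486,0.236474223334,-1.1849114576,0.480096305991,-0.0862991689294],[0.823081660319,-0.868594350352,0.181227774147,0.517700010768,0.181227774147,0.0758672584891,-0.868594350352,-0.0419157771672],[-0.50174209849,-0.239377834022,0.527877318691,0.453769346537,0.414548633384,-0.0962769903818,0.859234454646,-1.41803283036]],"pls_regression":{"loadings_X":[[-0.484261996452,-0.385529956591],[0.70144449611,-0.015157496715],[-0.312655767752,0.798719759608],[0.37582874817,0.346646893771],[0.185647678709,-0.30499111383]],"loadings_Y":[[-0.5223306496,-0.296490796922],[-0.684825397947,0.313032076363],[0.508118317742,0.243678614441],[0.000801242582606,0.868749019782]],"variates_X":[[-1.46291455796,1.66183273139],[0.724787014551,0.402315542596],[1.19109154383,0.134094259853],[1.6656022112,-0.233828985768],[-1.2639254889,1.31576191004],[0.966906611772,0.548507343273],[-1.35904399975,-1.93093843286],[-0.462503334732,-1.89774436853]],"variates_Y":[[-0.956275024095,0.0676607624049],[0.840326098607,0.496511206826],[0.289615265368,0.517120672773],[1.24344007898,-0.870752780589],[-1.60826232107,1.63497767497],[1.84045187287,0.918911249652],[-0.978712023632,-0.527514050229],[-0.670583947035,-2.2369147358]]},"pls_canonical":{"loadings_X":[[-0.484261996452,-0.378744248949],[0.70144449611,-0.0131368991399],[-0.312655767752,0.801480971602],[0.37582874817,0.351706574435],[0.185647678709,-0.300517808837]],"loadings_Y":[[-0.5223306496,-0.25969450042],[-0.684825397947,0.355837347513],[0.508118317742,0.211251873596],[0.000801242582606,0.872531486234]],"variates_X":[[-1.46291455796,1.65913782477],[0.724787014551,0.387234007488],[1.19109154383,0.149204892848],[1.6656022112,-0.238722791509],[-1.2639254889,1.31312497411],[0.966906611772,0.551816611625],[-1.35904399975,-1.92401651158],[-0.462503334732,-1.89777900776]],"variates_Y":[[-0.956275024095,0.0821718965049],[0.840326098607,0.456705640743],[0.289615265368,0.561462087686],[1.24344007898,-0.906279877453],[-1.60826232107,1.72334153536],[1.84045187287,0.791714381246],[-0.978712023632,-0.509131016344],[-0.670583947035,-2.19998464775]]},"spls":{"loadings_X":[[-0.322575514785,0],[0.946543732355,0],[0,0.999613658737],[0,0.0277944826569],[0,0]],"loadings_Y":[[-0.507113990791,0],[-0.649483966996,0.252486492349],[0.566573893645,0],[0,0.967600419172]]}}
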