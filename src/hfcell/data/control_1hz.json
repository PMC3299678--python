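{
 "m": 0.0038425435989318693,
 "h": 0.6240223197845595,
 "j": 0.6215412087195157,
 "d": 2.954612517295288e-06,
 "f": 0.9950982292484021,
 "fcaBj": 0.0255137130366951,
 "fcaBsl": 0.015562089583330274,
 "xtos": 0.0004425642994805956,
 "ytos": 0.7938644821153646,
 "xtof": 0.00044255556258461433,
 "ytof": 0.999995791858586,
 "xkr": 0.028376733520278682,
 "xks": 0.004298859109692664,
 "RyRr": 0.8923559000526639,
 "RyRo": 8.486675101950668e-07,
 "RyRi": 1.0237310378833604e-07,
 "NaBj": 3.4283751190739356,
 "NaBsl": 0.7480353601859474,
 "TnCL": 0.00933053630647925,
 "TnCHc": 0.11972947964362393,
 "TnCHm": 0.009502477978379139,
 "CaM": 0.0003103183954222809,
 "Myoc": 0.0021622501332970324,
 "Myom": 0.13731760292438636,
 "SRB": 0.002269113100415246,
 "SLLj": 0.00765431889230945,
 "SLLsl": 0.010073820698569954,
 "SLHj": 0.07515315679261152,
 "SLHsl": 0.11606415701539587,
 "Csqnb": 1.2298479043313275,
 "Ca_sr": 0.5834397991130859,
 "Naj": 8.290717885844042,
 "Nasl": 8.28971081271956,
 "Nai": 8.289894240633371,
 "Ki": 120.0,
 "Caj": 0.00018188053570223768,
 "Casl": 0.00010863162437577376,
 "Cai": 9.165625267461304e-05,
 "V": -81.39286283799211,
 "hL": 0.16228814611140896
}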