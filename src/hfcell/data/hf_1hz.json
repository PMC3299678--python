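{
 "m": 0.006103181397363825,
 "h": 0.5406315699853244,
 "j": 0.5245384198260639,
 "d": 4.295903912836196e-06,
 "f": 0.9935674376512776,
 "fcaBj": 0.0478172938067629,
 "fcaBsl": 0.02081875811146722,
 "xtos": 0.0005260915923506767,
 "ytos": 0.8399334244010234,
 "xtof": 0.0005260352441882741,
 "ytof": 0.9999934031138203,
 "xkr": 0.04328073449404829,
 "xks": 0.005029413296555344,
 "RyRr": 0.8148821516897116,
 "RyRo": 2.733015572135968e-06,
 "RyRi": 6.208514874112291e-07,
 "NaBj": 3.635819463346197,
 "NaBsl": 0.792817232073912,
 "TnCL": 0.010779674373219908,
 "TnCHc": 0.1219738333135511,
 "TnCHm": 0.008450324452448739,
 "CaM": 0.0003625556334737736,
 "Myoc": 0.0025212432230138993,
 "Myom": 0.1369574576432751,
 "SRB": 0.0026036593166901415,
 "SLLj": 0.014539290043250882,
 "SLLsl": 0.013475688514749184,
 "SLHj": 0.10716502357149583,
 "SLHsl": 0.1427724099982184,
 "Csqnb": 1.1306481782599638,
 "Ca_sr": 0.5001669932608986,
 "Naj": 9.264792530401566,
 "Nasl": 9.250943820488974,
 "Nai": 9.250922269824057,
 "Ki": 120.0,
 "Caj": 0.00034988211723013606,
 "Casl": 0.0001457219211851883,
 "Cai": 0.00010721056583582236,
 "V": -79.14720907338837,
 "hL": 0.09701010874329787
}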