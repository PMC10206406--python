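name,lifespan_d,density_kg_m3,demand_g_capita_d,cold_factor,production_demand_ratio,m1,m2,m3,m4,m5,m6,m7,m8,m9,m10,m11,m12
potato,21,650,90,1.0,0.4,4,4,0,0,0,0,0,0,0,0,0,4
onion,15,500,45,1.0,1.3,0,0,4,4,4,0,0,0,0,0,0,0
tomato,6,600,45,1.0,1.5,1.4,1.3,1.2,1.0,0.8,0.6,0.6,0.8,1.0,1.1,1.2,1.0
brinjal,4,400,50,1.0,5.2,1.1,1.1,1.0,1.0,0.9,0.8,0.8,0.9,1.0,1.1,1.2,1.1
cabbage,7,350,36,1.0,1.4,1.6,1.4,1.0,0.7,0.5,0.4,0.4,0.5,0.8,1.2,1.6,1.9
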