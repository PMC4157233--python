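electrons,asp_proton,prop_proton,is_ts,reduced_cluster,oxidized_cluster
0,Asp274,Propionate,0,0.00,0.00
0,Asp274,C18,0,20.34,19.98
0,C17,Propionate,0,25.36,25.25
1,Asp274,Propionate,0,-64.05,-64.70
1,Asp274,C18,0,-69.64,-70.17
1,C17,Propionate,0,-65.73,-66.24
1,C17,C18,0,-72.20,-72.14
2,Asp274,C18,0,-126.58,-127.57
2,C17,Propionate,0,-131.10,-132.04
2,C17,C18,0,-169.60,-170.10
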