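electrons,asp_proton,prop_proton,is_ts,oniom
0,Asp274,Propionate,0,0.00
0,Asp274,C18,0,23.5
0,C17,Propionate,0,37.8
1,Asp274,Propionate,0,-175.2
1,Asp274,C18,0,-182.6
1,C17,Propionate,0,-166.4
1,C17,C18,0,-184.06
2,Asp274,Propionate,0,-288.9
2,Asp274,C18,0,-310.3
2,C17,Propionate,0,-307.6
2,C17,C18,0,-355.3
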