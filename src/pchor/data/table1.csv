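electrons,asp_proton,prop_proton,is_ts,eps4,eps10,eps20,eps78
0,Asp274,Propionate,0,0.0,0.0,0.0,0.0
0,Asp274,Propionate...C18,1,24.0,24.7,25.0,25.2
0,Asp274,C18,0,19.7,19.8,19.9,19.9
0,Asp274...C17,Propionate,1,31.3,31.4,31.5,31.6
0,C17,Propionate,0,26.3,25.3,25.0,24.7
1,Asp274,Propionate,0,-62.2,-67.4,-69.3,-70.7
1,Asp274...C17,Propionate,1,-49.1,-53.8,-55.5,-56.8
1,C17,Propionate,0,-64.5,-70.5,-72.6,-74.2
1,Asp274,Propionate...C18,1,-53.3,-58.3,-60.0,-61.3
1,Asp274,C18,0,-68.5,-73.9,-75.9,-77.3
1,Asp274...C17,C18,1,-50.2,-55.1,-56.7,-58.0
1,C17,Propionate...C18,1,-54.2,-59.7,-61.6,-63.0
1,C17,C18,0,-68.4,-75.6,-78.1,-79.9
1,C18*,Propionate,0,-53.9,-59.6,-61.6,-63.1
1,Asp274,C17*,0,-51.9,-58.4,-60.7,-62.5
2,Asp274,Propionate,0,-101.5,-121.2,-128.1,-133.4
2,Asp274...C17,Propionate,1,-94.6,-112.7,-119.0,-123.8
2,C17,Propionate,0,-123.3,-142.1,-148.6,-153.5
2,Asp274,Propionate...C18,1,-98.2,-116.4,-122.8,-127.6
2,Asp274,C18,0,-119.2,-138.7,-145.5,-150.7
2,C17,Propionate...C18,1,-126.8,-145.3,-151.7,-156.6
2,Asp274...C17,C18,1,-124.9,-143.7,-150.2,-155.1
2,C17,C18,0,-160.1,-179.1,-185.6,-190.5
2,C18*,Propionate,0,-112.5,-130.5,-136.7,-141.4
2,Asp274,C17*,0,-113.4,-132.9,-139.6,-144.8
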