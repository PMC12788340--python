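participant_id,sport,trials,left_strides,right_strides
1,VFLW,4,8,8
2,VFLW,4,8,4
3,VFLW,4,8,4
4,VFL,4,4,7
5,VFLW,4,4,4
6,AFLW,4,4,8
7,VFLW,4,4,8
8,VFLW,4,5,7
9,AFLW,4,8,4
10,AFL,4,4,4
11,VFL,4,8,4
12,VFL,4,4,6
13,VFLW,4,4,8
14,VFLW,4,4,7
15,VFLW,4,8,4
16,Track and field,4,7,4
17,AFLW,4,8,4
18,AFLW,4,4,8
19,VFLW,4,8,4
20,A-League Academy,4,4,8
21,A-League Academy,4,4,8
22,A-League Academy,4,8,4
23,A-League Academy,4,4,6
Total,,92,132,133
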