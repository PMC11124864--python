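attribute,M,O,A,I,Q,R,printed_result
Wheelchair exterior design,15,4,68,13,0,0,A
Wheelchair posture adjustment,72,11,15,2,0,0,M
Automatically travels up and down the stairs,90,4,6,0,0,0,M
Style/fashion,22,54,16,5,3,0,O
Night illumination,17,21,16,43,3,0,I
Mobile terminal control,14,8,18,52,4,0,I
Easy mobility to and from bed,32,0,68,0,0,0,A
Wheelchair seats raised,32,12,56,0,0,0,A
User body data sharing,0,0,1,23,4,72,R
Long single working hours,27,54,16,3,0,0,O
Quick charge,30,48,15,7,0,0,O
Safe and efficient,97,1,2,0,0,0,M
Wheelchair entertainment function,1,0,0,20,11,68,R
Wheelchair e-book,0,5,20,21,8,46,R
Wheelchair color scheme of choice,10,1,13,67,9,0,I
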