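item,label,delta,david,rob
ddifmd011,Puts cube in and out of a box,46.0,1,1
ddifmm012,Plays 'give and take' (M; can ask parents),46.5,1,0
ddicmm037,Uses two words with comprehension,50.1,1,1
ddigmm066,"Crawls, abdomen off the floor (M; can ask parents)",46.1,1,1
ddigmm067,Walks while holding onto play-pen or furniture,46.1,,0
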