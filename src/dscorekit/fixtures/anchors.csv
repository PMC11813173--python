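item,label,value
ddigmd057,Lifts head to 45 degrees on prone position,20
ddigmd063,Sits in stable position without support,40
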