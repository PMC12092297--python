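term,weight
_intercept,0.0
happy,2.0
good,1.0
love,1.5
great,1.2
glad,1.0
hope,0.8
sad,-2.0
angry,-1.5
hate,-1.8
hurt,-1.0
cry,-1.2
afraid,-1.0
worried,-0.8
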