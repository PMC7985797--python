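trait,intercept,cogproc,work,social,posemo,negemo
openness,0.0,10.0,0.0,0.0,0.0,0.0
conscientiousness,0.0,0.0,10.0,0.0,0.0,0.0
extraversion,0.0,0.0,0.0,10.0,0.0,0.0
agreeableness,0.0,0.0,0.0,0.0,10.0,0.0
neuroticism,0.0,0.0,0.0,0.0,0.0,10.0
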