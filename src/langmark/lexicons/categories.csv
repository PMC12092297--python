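category,term
pronoun_i,i
pronoun_i,me
pronoun_i,my
pronoun_i,mine
pronoun_i,myself
social,friend*
social,family
social,mother
social,father
social,people
social,together
negemo,sad
negemo,angry
negemo,hate
negemo,hurt
negemo,cry
negemo,afraid
negemo,worr*
posemo,happy
posemo,good
posemo,love
posemo,great
posemo,glad
posemo,hope
health,sick
health,ill*
health,pain*
health,ache
health,doctor
health,tired
health,hospital
cogproc,think
cogproc,know
cogproc,because
cogproc,reason
cogproc,understand
cogproc,cause
article,a
article,an
article,the
body,head
body,arm
body,leg
body,heart
body,stomach
body,back
body,hand
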