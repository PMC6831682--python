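an	-|-|a|n
ceng	tsʰ|-|ə|ŋ
dai	t|-|a|ɪ
du	t|-|u|-
guo	k|u|o|-
jia	tɕ|i|a|-
jian	tɕ|i|ɛ|n
jie	tɕ|i|ɛ|-
jing	tɕ|-|i|ŋ
jue	tɕ|y|ɛ|-
ma	m|-|a|-
mai	m|-|a|ɪ
man	m|-|a|n
shuai	ʂ|u|a|ɪ
shuan	ʂ|u|a|n
tu	tʰ|-|u|-
wai	-|u|a|ɪ
wan	-|u|a|n
wu	-|-|u|-
xiang	ɕ|i|a|ŋ
xie	ɕ|i|ɛ|-
xiong	ɕ|i|o|ŋ
yi	-|-|i|-
ye	-|i|ɛ|-
zai	ts|-|a|ɪ
zan	ts|-|a|n
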