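# Toy word list (tonal pinyin), one entry per line.
# Syllable+tone combinations NOT listed here are nonwords; zai2 is deliberately
# absent (it corresponds to no Chinese character).
an3
an4
ceng1
ceng2
dai1
dai3
dai4
du2
du4
guo1
guo2
guo4
jia1
jia4
jian1
jian4
jie1
jie2
jie4
jing3
jue1
jue2
ma1
ma3
ma4
mai3
mai4
man2
man4
shuai4
shuan4
tu2
tu3
wai4
wan1
wan4
wu2
wu4
xiang3
xiang4
xie1
xie4
xiong2
yi1
yi4
ye1
ye4
zai1
zai3
zai4
zan4
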