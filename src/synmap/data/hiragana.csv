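symbol,script,position,name_phonemes,familiarity
あ,hiragana,1,a,
い,hiragana,2,i,
う,hiragana,3,u,
え,hiragana,4,e,
お,hiragana,5,o,
か,hiragana,6,k|a,
き,hiragana,7,k|i,
く,hiragana,8,k|u,
け,hiragana,9,k|e,
こ,hiragana,10,k|o,
さ,hiragana,11,s|a,
し,hiragana,12,s|i,
す,hiragana,13,s|u,
せ,hiragana,14,s|e,
そ,hiragana,15,s|o,
た,hiragana,16,t|a,
ち,hiragana,17,t|i,
つ,hiragana,18,t|u,
て,hiragana,19,t|e,
と,hiragana,20,t|o,
な,hiragana,21,n|a,
に,hiragana,22,n|i,
ぬ,hiragana,23,n|u,
ね,hiragana,24,n|e,
の,hiragana,25,n|o,
は,hiragana,26,h|a,
ひ,hiragana,27,h|i,
ふ,hiragana,28,h|u,
へ,hiragana,29,h|e,
ほ,hiragana,30,h|o,
ま,hiragana,31,m|a,
み,hiragana,32,m|i,
む,hiragana,33,m|u,
め,hiragana,34,m|e,
も,hiragana,35,m|o,
や,hiragana,36,y|a,
ゆ,hiragana,37,y|u,
よ,hiragana,38,y|o,
ら,hiragana,39,r|a,
り,hiragana,40,r|i,
る,hiragana,41,r|u,
れ,hiragana,42,r|e,
ろ,hiragana,43,r|o,
わ,hiragana,44,w|a,
を,hiragana,45,w|o,
ん,hiragana,46,N,
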