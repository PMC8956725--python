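code,description,example
IF-PD,inferiority feelings about physical defects,"I haven't been praised for my appearance, which makes me feel inferior"
IF-LA,inferiority feelings about love and affection,I feel inferior to my brilliant girlfriend
IF-FB,inferiority feelings about family background,My family environment has made me feel inferior since childhood
IF-P,inferiority feelings about personality,Being sensitive makes me lack security and feel inferior
IF-PE,inferiority feelings about personal experiences,It is my childhood that makes me inferior; I took care of myself like a wild child without parents
IF-SI,inferiority feelings about social interaction,"Every time I'm in a crowded place, I feel so scared and inferior that I dare not to speak to others"
IF-L,inferiority feelings about learning,I feel too inferior to look at my English teacher in every class
IF-A,inferiority feelings about abilities,"Sometimes I feel shy, useless and inferior to others, which makes me feel more and more inferior"
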