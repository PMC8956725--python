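group,token,gloss
A1,认为,think
A1,以为,feel
A2,自己,oneself
A2,本人,myself
A2,我,I
A3,不如,inferior to
A3,比不过,not equal to
A4,别人,other people
A4,他,he
A4,她,she
A4,他/她们,them
A5,低落,feel low
A5,沮丧,depressed
A5,颓唐,dejected
A5,萎靡,downhearted
A5,消沉,despondent
A6,悲伤,sadness
A6,心酸,feel sad
A6,悲戚,grief
A6,伤感,unhappiness
A6,悲哀,sadness
A6,哀痛,mourning
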