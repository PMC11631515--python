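%
1	negate
2	article
3	posemo
4	negemo
5	family
6	social
7	insight
8	tentat
9	see
10	hear
11	nonflu
12	assent
13	focuspast
14	focusfuture
15	health
16	body
17	risk
18	reward
19	home
20	work
%
no	1
not	1
never	1
nothing	1
don't	1
can't	1
the	2
a	2
an	2
happ*	3
glad	3
good	3
nice	3
love	3
sad	4
bad	4
hurt	4
angry	4
afraid	4
upset	4
mother	5
sister	5
son	5
daughter	5
famil*	5
friend	6
people	6
neighbor	6
visit*	6
think	7
know	7
believe	7
understand*	7
remember	7
maybe	8
perhaps	8
guess	8
might	8
see	9
look	9
watch*	9
hear	10
listen*	10
sound	10
um	11
uh	11
er	11
ah	11
mm	11
hmm	11
yeah	12
okay	12
yes	12
right	12
sure	12
was	13
were	13
did	13
yesterday	13
ago	13
before	13
will	14
gonna	14
tomorrow	14
soon	14
doctor	15
nurse	15
medicine	15
pill	15
sick	15
dizzy	15
arm	16
leg	16
chest	16
heart	16
blood	16
breath	16
risk	17
danger*	17
fall	17
worse	17
better	18
improve*	18
help	18
strong	18
home	19
house	19
kitchen	19
bed	19
work	20
job	20
retire*	20
walk	20
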