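%
1	cogproc
2	work
3	social
4	posemo
5	negemo
%
abstract	1
afraid	5
angry	5
anxious	5
art	1
awful	5
busy	2
care	4
careful	2,4
chat	3
complete	2
create	1
creative	1
crowd	3
cry	5
curious	1
dance	3
discipline	2
dream	1
duty	2
effort	2
everybody	3
explore	1
fear*	5
finish	2
friend*	3
fun	3
gentle	4
goal	2
good	4
happi*	4
hate	5
helpful	4
idea*	1
imagin*	1
kind	4
lonely	5
love*	4
meet	3
nervous	5
nice	4
novel	1
organiz*	2
party	3
plan*	2
ponder	1
question*	1
sad	5
schedul*	2
share	4
social	3
stress*	5
sweet	4
talk*	3
task*	2
terrible	5
thank*	4
theory	1
think	1
tidy	2
together	3
upset	5
warm	4
wonder	1
work*	2
worr*	5
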