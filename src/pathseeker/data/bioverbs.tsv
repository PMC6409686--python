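# Biomedical relation verbs with polarity class (INCREASE/DECREASE/NEUTRAL)
abolish	DECREASE
abrogate	DECREASE
accelerate	INCREASE
activate	INCREASE
aggravate	INCREASE
amplify	INCREASE
antagonize	DECREASE
associate	NEUTRAL
attenuate	DECREASE
augment	INCREASE
become	NEUTRAL
bind	NEUTRAL
block	DECREASE
catalyze	NEUTRAL
cause	INCREASE
conserve	NEUTRAL
correlate	NEUTRAL
decrease	DECREASE
degrade	DECREASE
delete	DECREASE
deplete	DECREASE
depress	DECREASE
differ	NEUTRAL
diminish	DECREASE
disrupt	DECREASE
down-regulate	DECREASE
downregulate	DECREASE
elevate	INCREASE
elicit	INCREASE
encode	NEUTRAL
enhance	INCREASE
exert	NEUTRAL
express	INCREASE
facilitate	INCREASE
identify	NEUTRAL
impair	DECREASE
improve	INCREASE
inactivate	DECREASE
increase	INCREASE
induce	INCREASE
inhibit	DECREASE
interact	NEUTRAL
lead	NEUTRAL
lower	DECREASE
mediate	NEUTRAL
modulate	NEUTRAL
neutralize	DECREASE
observe	NEUTRAL
occur	NEUTRAL
phosphorylate	INCREASE
potentiate	INCREASE
predict	NEUTRAL
present	NEUTRAL
prevent	DECREASE
promote	INCREASE
raise	INCREASE
reduce	DECREASE
regulate	NEUTRAL
repress	DECREASE
restore	INCREASE
result	NEUTRAL
rise	INCREASE
separate	NEUTRAL
serve	NEUTRAL
silence	DECREASE
stabilize	INCREASE
stimulate	INCREASE
suggest	NEUTRAL
suppress	DECREASE
trigger	INCREASE
up-regulate	INCREASE
upregulate	INCREASE
use	NEUTRAL
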