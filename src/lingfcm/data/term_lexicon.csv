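phrase,level
did not predict,VL
not important,VL
small and short lived,VL
might be more limited,L
likely to,L
a risk factor,L
address needs,L
good chance,L
can diminish but not necessarily,L
lack,L
leads to,L
disadvantage,L
to restriction,L
likely,L
may experience,L
may trigger,L
might be,L
not significant,L
primary risk factor,L
risk,L
risk factor,L
appear to increase,M
associated,M
at risk,M
benefit,M
common and of concern,M
considerable,M
ongoing,M
cope,M
effective,M
implicated,M
increase risk,M
increased risk,M
increases chances of,M
independently associated,M
less likely,M
lower levels,M
more difficult,M
more likely,M
most common,M
most effective,M
not uncommon,M
relatively,M
relatively low,M
relatively low rates,M
remain problematic,M
restricts,M
thereby increase,M
usually,M
widely used to support,M
associated with,M
crucial,H
highly predictive,H
important role,H
important causal factor,H
important means,H
key factor,H
major contributor,H
most important,H
much more likely,H
much higher,H
play important role,H
play an important role,H
positive and significant,H
powerful,H
powerful instrument,H
significant correlates,H
significant,H
significantly associated,H
significantly and independently,H
significant proportion,H
statistically significant,H
strong,H
strongly associated,H
strong connection,H
strong correlation,H
strong determinant,H
strong effect,H
strong evidence,H
substantial,H
substantially,H
bulk of,H
the bulk of responsibility,H
positive/negative and significant,H
significant connection,H
strong positive,H
strong positive correlation,H
run a great risk,H
thwarted,H
critical,VH
evidence indicates,VH
extensive,VH
more prominently,VH
profound,VH
profound effect,VH
significant and positive,VH
significantly and strongly,VH
significantly increase,VH
significantly lower,VH
significantly more,VH
significantly more likely,VH
significantly positive,VH
tremendous,VH
tremendous strains,VH
very high,VH
vital,VH
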