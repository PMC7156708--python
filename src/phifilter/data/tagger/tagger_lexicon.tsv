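# Lexical table for the rule-based tagger: lowercase word <TAB> Penn tag.
# Consulted for lowercase words and for capitalized words at sentence
# starts; a capitalized sentence opener found here is NOT treated as a
# proper noun, which is what lets "White fluid found at..." keep "White".
white	JJ
brown	JJ
black	JJ
green	JJ
gray	JJ
grey	JJ
red	JJ
blue	JJ
yellow	JJ
pale	JJ
clear	JJ
normal	JJ
stable	JJ
severe	JJ
mild	JJ
moderate	JJ
acute	JJ
chronic	JJ
general	JJ
physical	JJ
chief	JJ
social	JJ
serial	JJ
current	JJ
new	JJ
young	JJ
soft	JJ
steady	JJ
regular	JJ
patient	NN
patients	NNS
history	NN
exam	NN
assessment	NN
plan	NN
impression	NN
complaint	NN
medication	NN
medications	NNS
allergies	NNS
labs	NNS
vitals	NNS
review	NN
systems	NNS
skin	NN
lungs	NNS
chest	NN
abdomen	NN
extremities	NNS
wound	NN
gait	NN
strength	NN
fluid	NN
pain	NN
blood	NN
pressure	NN
heart	NN
rate	NN
temperature	NN
results	NNS
contact	NN
office	NN
account	NN
security	NN
age	NN
home	NN
family	NN
mother	NN
father	NN
sister	NN
brother	NN
daughter	NN
son	NN
wife	NN
husband	NN
today	NN
tomorrow	NN
yesterday	NN
summer	NN
winter	NN
spring	NN
fall	NN
autumn	NN
knee	NN
child	NN
stone	NN
snow	NN
rice	NN
license	NN
record	NN
number	NN
visit	NN
portal	NN
access	NN
consent	NN
form	NN
device	NN
campus	NN
follow	VB
followup	NN
continue	VB
start	VB
started	VBD
stop	VB
increase	VB
increased	VBD
decrease	VB
decreased	VBD
denies	VBZ
reports	VBZ
states	VBZ
notes	VBZ
walks	VBZ
seen	VBN
admitted	VBN
discharged	VBN
presents	VBZ
returned	VBD
discussed	VBD
reviewed	VBD
checked	VBD
verified	VBD
billed	VBD
confirmed	VBD
signed	VBD
countersigned	VBD
found	VBD
rose	VBD
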