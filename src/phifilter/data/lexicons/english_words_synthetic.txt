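# SYNTHETIC fixture: common-English vocabulary standing in for a
# most-frequent-words list plus common verb tenses. One token per line.
the
be
to
of
and
a
an
in
that
have
has
had
it
for
not
on
with
he
she
as
you
do
does
did
at
this
but
his
her
by
from
they
we
say
says
said
or
will
my
one
all
would
there
their
what
so
up
out
if
about
who
get
gets
got
which
go
goes
went
me
when
make
makes
made
can
like
time
no
just
him
know
knows
knew
take
takes
taken
took
people
into
year
years
your
good
some
could
them
see
sees
saw
seen
other
than
then
now
look
looks
looked
only
come
comes
came
its
over
think
thinks
thought
also
back
after
use
uses
used
two
three
four
five
six
seven
eight
nine
ten
how
our
work
works
worked
first
second
third
well
way
even
new
want
wants
wanted
because
any
these
give
gives
given
gave
day
days
most
us
is
are
was
were
been
being
am
very
much
more
less
least
many
few
each
every
both
between
under
again
further
once
here
where
why
while
during
before
against
above
below
off
down
should
may
might
must
shall
need
needs
needed
feel
feels
felt
feeling
better
worse
best
worst
today
tomorrow
yesterday
morning
evening
night
week
weeks
month
months
hour
hours
minute
minutes
without
within
since
still
yet
already
often
sometimes
always
never
usually
around
near
far
left
right
old
own
same
able
early
late
recent
recently
small
large
long
short
high
low
several
report
reports
reported
reporting
state
states
stated
note
notes
noted
noting
find
finds
found
finding
findings
show
shows
showed
shown
appear
appears
appeared
remain
remains
remained
continue
continues
continued
start
starts
started
starting
stop
stops
stopped
increase
increased
increasing
decrease
decreased
decreasing
improve
improves
improved
improving
worsen
worsened
worsening
change
changes
changed
return
returns
returned
returning
visit
visits
visited
follow
follows
followed
following
followup
plan
plans
planned
discuss
discusses
discussed
discussing
review
reviews
reviewed
reviewing
check
checks
checked
checking
confirm
confirms
confirmed
verify
verifies
verified
sign
signs
signed
bill
bills
billed
update
updates
updated
list
lists
listed
advise
advised
recommend
recommends
recommended
schedule
scheduled
complete
completed
receive
received
give
given
deny
denies
denied
tolerate
tolerates
tolerated
reveal
reveals
revealed
present
presents
presented
presenting
feel
felt
live
lives
lived
living
alone
family
home
house
mother
father
sister
brother
daughter
son
wife
husband
parent
parents
caregiver
person
people
man
woman
name
number
record
account
contact
phone
address
email
letter
form
consent
file
office
clinic
hospital
ward
unit
room
bed
department
service
team
staff
doctor
nurse
provider
physician
surgeon
specialist
therapist
patient
patients
visitor
appointment
procedure
surgery
operation
therapy
treatment
test
tests
tested
result
results
value
values
level
levels
normal
abnormal
stable
unstable
severe
mild
moderate
acute
chronic
active
inactive
positive
negative
clear
cloudy
regular
irregular
soft
hard
firm
tender
nontender
steady
unsteady
white
brown
black
green
gray
grey
red
blue
yellow
pale
warm
cool
dry
moist
good
fair
poor
general
overall
detail
details
detailed
further
additional
possible
likely
unlikely
necessary
important
significant
risk
risks
benefit
benefits
concern
concerns
issue
issues
problem
problems
question
questions
answer
answers
history
story
course
status
condition
conditions
symptom
symptoms
sign
signs
cause
causes
effect
effects
side
prevention
care
health
healthy
illness
disease
diagnosis
prognosis
medication
medications
medicine
drug
drugs
dose
doses
dosage
tablet
tablets
capsule
capsules
pill
pills
daily
twice
weekly
monthly
nightly
morning
bedtime
meal
meals
food
water
diet
exercise
rest
sleep
weight
height
score
scale
range
limit
limits
age
birth
born
alive
alert
awake
oriented
cooperative
comfortable
distress
complaint
complaints
pain
ache
pressure
feeling
sensation
strength
weakness
motion
movement
walk
walking
walks
walked
stand
standing
sit
sitting
fall
falls
fell
fallen
breath
breathing
cough
coughing
fever
chills
sweats
nausea
vomiting
appetite
fatigue
tired
dizzy
headache
swelling
redness
rash
itching
bleeding
bruising
numbness
tingling
burning
site
area
region
surface
wound
incision
dressing
bandage
suture
sutures
healing
healed
infection
infected
drainage
discharge
specimen
sample
culture
imaging
scan
film
study
studies
campus
portal
access
security
social
serial
device
current
verified
system
systems
paper
chart
summary
order
orders
ordered
instruction
instructions
education
material
materials
copy
sent
send
sends
sending
call
calls
called
calling
speak
speaks
spoke
spoken
discussion
agreement
refused
refuses
refuse
agreed
agrees
agree
understand
understands
understood
explain
explains
explained
assessment
physical
repeat
symmetric
complication
complications
allergy
allergies
sound
sounds
license
countersigned
absent
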