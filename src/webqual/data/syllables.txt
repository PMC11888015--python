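# Hand-syllabified word -> syllable-count table.
# Format: one "word count" pair per line; '#' starts a comment.
# Lookup is case-insensitive. Words not listed fall back to the
# vowel-group heuristic in webqual._syllables.
a 1
an 1
and 1
ask 1
felt 1
part 1
saw 1
see 1
smith 1
things 1
watch 1
way 1
are 1
as 1
at 1
be 1
bed 1
been 1
brain 1
but 1
by 1
calm 1
can 1
care 1
cat 1
chair 1
change 1
clear 1
could 1
day 1
dog 1
do 1
door 1
down 1
drink 1
each 1
fast 1
few 1
first 1
food 1
for 1
friend 1
from 1
get 1
good 1
had 1
hand 1
has 1
have 1
he 1
head 1
health 1
heart 1
help 1
her 1
here 1
high 1
him 1
his 1
home 1
how 1
if 1
in 1
is 1
it 1
its 1
just 1
large 1
last 1
left 1
less 1
light 1
long 1
loud 1
low 1
made 1
mat 1
may 1
mild 1
mind 1
more 1
most 1
must 1
need 1
new 1
night 1
no 1
noise 1
not 1
now 1
nurse 1
of 1
old 1
on 1
one 1
or 1
our 1
out 1
pain 1
plan 1
rest 1
room 1
same 1
sat 1
she 1
short 1
sick 1
sign 1
sleep 1
slow 1
small 1
so 1
some 1
soon 1
staff 1
stay 1
still 1
stress 1
such 1
sun 1
talk 1
team 1
test 1
than 1
that 1
the 1
their 1
them 1
then 1
there 1
these 1
they 1
this 1
those 1
three 1
through 1
time 1
to 1
two 1
walk 1
ward 1
was 1
we 1
week 1
well 1
were 1
what 1
when 1
where 1
who 1
why 1
will 1
with 1
would 1
year 1
yes 1
you 1
your 1
about 2
affect 2
affects 2
older 2
problems 2
website 2
after 2
also 2
answer 2
any 2
because 2
before 2
better 2
body 2
careful 2
causes 2
common 2
daily 2
doctor 2
drinking 2
early 2
eating 2
fever 2
gentle 2
harmful 2
hearing 2
helpful 2
illness 2
later 2
lessen 2
listen 2
little 2
many 2
member 2
morning 2
moving 2
nurses 2
offer 2
often 2
only 2
open 2
order 2
over 2
painful 2
partner 2
patient 2
people 2
person 2
problem 2
question 2
reason 2
restful 2
restless 2
simple 2
sleeping 2
sudden 2
symptom 2
talking 2
thinking 2
treatment 2
under 2
very 2
visit 2
waking 2
walking 2
water 2
weekly 2
window 2
worry 2
attention 3
behavior 3
condition 3
confusion 3
dementia 3
develop 3
disorder 3
energy 3
family 3
fluctuates 3
hospital 3
important 3
infection 3
management 3
medical 3
medicine 3
memory 3
prevention 3
recover 3
remember 3
serious 3
suddenly 3
together 3
treatable 3
understand 3
ability 4
activity 4
community 4
complication 4
delirium 4
education 4
environment 4
experience 4
gobbledygook 4
identify 4
information 4
material 4
medication 4
necessary 4
ordinary 4
population 4
recovery 4
security 4
situation 4
television 4
unfamiliar 4
administration 5
disorientation 6
communication 5
hallucination 5
investigation 5
organization 5
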