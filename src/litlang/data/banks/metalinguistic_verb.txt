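# Meta-linguistic verbs: verbs of speaking/dialogue, child register, all
# inflections enumerated (matching is surface-form only; overgeneralized
# irregulars such as "sayed" will be missed).
# "like" (quotative) is excluded by default; enable via config if desired.
say
says
said
saying
tell
tells
told
telling
ask
asks
asked
asking
yell
yells
yelled
yelling
shout
shouts
shouted
shouting
scream
screams
screamed
screaming
whisper
whispers
whispered
whispering
call
calls
called
calling
talk
talks
talked
talking
speak
speaks
spoke
speaking
answer
answers
answered
answering
reply
replies
replied
replying
laugh
laughs
laughed
laughing
cry
cries
cried
crying
sing
sings
sang
singing
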