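# Meta-cognitive verbs: verbs of thought, feeling, and character perspective,
# child register, inflections enumerated.
think
thinks
thought
thinking
know
knows
knew
knowing
wonder
wonders
wondered
wondering
decide
decides
decided
deciding
remember
remembers
remembered
remembering
forget
forgets
forgot
forgetting
believe
believes
believed
believing
wish
wishes
wished
wishing
hope
hopes
hoped
hoping
guess
guesses
guessed
guessing
imagine
imagines
imagined
imagining
pretend
pretends
pretended
pretending
realize
realizes
realized
realizing
figure
figured
feel
feels
felt
feeling
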