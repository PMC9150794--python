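# Coordinating conjunctions (FANBOYS). "then" is deliberately absent: although it
# often appears alongside "and" in child narratives, it is an adverb, not a
# coordinator, and counting it here would double-dip with the adverb element.
for
and
nor
but
or
yet
so
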