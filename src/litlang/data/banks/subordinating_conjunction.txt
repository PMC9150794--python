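# Subordinating conjunctions / subordinators common in child narrative register
# (ages roughly 5-10). Surface forms only; matching is exact, no stemming.
because
since
when
whenever
while
if
unless
until
till
before
after
although
though
therefore
cause
cuz
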