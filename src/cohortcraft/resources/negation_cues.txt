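# Negation cue dictionary: one cue per line, multi-word allowed.
# Lines starting with '#' are comments.
not
no
without
except
except for
other than
free of
free from
absence of
absent
exclude
excluding
excluded
neither
nor
denies
denied
negative for
lack of
lacking
rule out
ruled out
no evidence of
no history of
unable to
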