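phrase,direction
prior to,before
prior,before
before,before
preceding,before
previous to,before
leading up to,before
earlier than,before
pre,before
after,after
post,after
following,after
since,after
subsequent to,after
from,after
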