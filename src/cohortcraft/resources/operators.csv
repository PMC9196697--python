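phrase,symbol
up to,<=
at least,>=
at most,<=
or higher,>=
or more,>=
or greater,>=
or above,>=
or over,>=
and above,>=
and over,>=
or less,<=
or lower,<=
or fewer,<=
or below,<=
and under,<=
less than,<
fewer than,<
more than,>
greater than,>
no more than,<=
no less than,>=
no fewer than,>=
a minimum of,>=
minimum of,>=
a maximum of,<=
maximum of,<=
over,>
above,>
exceeding,>
under,<
below,<
within,<=
equal to,=
≥,>=
≤,<=
>=,>=
<=,<=
<>,<>
>,>
<,<
=,=
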