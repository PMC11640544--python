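# NF-kB pathway gene panel: canonical and non-canonical regulators.
NFKBIA
RELA
IKBKG
NFKB2
RELB
CHUK
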