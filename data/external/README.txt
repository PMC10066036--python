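Optional external input.

Place the Fionnbharth phage genome FASTA here as fionnbharth.fasta
(available from phagesdb.org) to have the acceptance script and the
genome acceptance test report the real genome GC% instead of the
synthetic stand-in.
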