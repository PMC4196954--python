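# Synthetic default signatures for PPDK-vs-PEPS discrimination.
#
# These exact-string motifs are the ones the sequence generator plants; they
# stand in for the real N-terminal nucleotide-binding-domain signatures,
# which real-data users must transcribe from a domain database and supply
# via their own signature file (same YAML layout).
ppdk:
  - name: ppdk_nbd_core
    pattern: GGKGANLAEM
    window_start: 1
    window_end: 160
peps:
  - name: peps_nterm_core
    pattern: HQDWSNLTRE
    window_start: 1
    window_end: 160
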