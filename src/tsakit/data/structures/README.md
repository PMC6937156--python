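# Deposited structure inputs

Place plain-text coordinate files `6GO2.pdb` (CPT+SLeu) and `6SN6.pdb`
(CPT+SGlu) in this directory to enable the real-data geometry checks, or
point `TSAKIT_STRUCTURE_DIR` at a directory containing them.

With network access:

    tsakit fetch

downloads both entries from https://files.rcsb.org/.
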