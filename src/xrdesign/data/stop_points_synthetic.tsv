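# Synthetic stop-point records for the validated synthetic xrRNA
# constructs.  Stop positions (1-based, 5'-most nucleotide of the
# XRN1-resistant fragment, on the full leader+xrRNA substrate) are
# reconstructed from the published substrate and resistant-product
# lengths of the degradation assay; they are stand-ins for the raw
# amplicon-sequencing stop-point table, which is not redistributed here.
construct	substrate_len	stop_pos	read_count
syn-xrRNA2	85	25	52000
syn-xrRNA3	83	21	48000
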