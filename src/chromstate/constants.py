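"""Shared sentinel values for ternary observations and segmentations."""

# Ternary observation matrices hold {0, 1, MISSING}. On disk (ChromHMM
# binarized text) MISSING is written as "2"; in memory we use -1 so that
# boolean comparisons against 0/1 stay unambiguous.
MISSING: int = -1

# Per-bin state labels: -1 means the max posterior did not exceed 0.5.
UNASSIGNED: int = -1
UNASSIGNED_NAME: str = "unassigned"
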