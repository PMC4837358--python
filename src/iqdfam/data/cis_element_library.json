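[
  {
    "element_id": "S000176",
    "consensus": "NNNNNN",
    "description": "Drought-stress element (PLACE ID). Consensus is USER-SUPPLIED: the published survey reports only the PLACE identifier, not the motif sequence; replace this placeholder with the PLACE consensus before scanning real promoters."
  },
  {
    "element_id": "S000415",
    "consensus": "NNNNNN",
    "description": "Drought-stress element (PLACE ID). Consensus is USER-SUPPLIED; see S000176 note."
  },
  {
    "element_id": "S000457",
    "consensus": "NNNNNN",
    "description": "Wound-stress element (PLACE ID). Consensus is USER-SUPPLIED; see S000176 note."
  }
]
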