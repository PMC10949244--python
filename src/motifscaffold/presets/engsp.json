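{
  "_comment": "GH101 active-site scaffold preset. Template: EngSP catalytic domain (PDB 5A55, chain A), three discontinuous motifs in author numbering, compiled onto a 290-residue design. Linker bounds, internal gap segments and medium-weight strand ranges are editable modelling choices; the six named fixed identities are the substrate-contacting residues, the null entries are constrained positions whose identities must be supplied by the user before a sequence-constrained run.",
  "template_pdb": "5A55",
  "template_chain": "A",
  "length": 290,
  "linkers": [[0, 8], [2, 12], [2, 12], [0, 8]],
  "motifs": [
    {
      "name": "m1",
      "span": [603, 705],
      "gaps": [[640, 645]],
      "weights": {
        "medium": [[615, 622], [650, 656], [684, 690]],
        "heavy": [627, 656, 658, 659, 660, 661, 662, 690, 692, 694, 695, 696, 697]
      },
      "fixed": {
        "627": null, "656": null, "658": "D", "659": null, "660": null,
        "661": "H", "662": null, "690": null, "692": null, "694": "H",
        "695": null, "696": "N", "697": null
      }
    },
    {
      "name": "m2",
      "span": [722, 800],
      "gaps": [[745, 748]],
      "weights": {
        "medium": [[730, 737], [770, 777]],
        "heavy": [724, 726, 762, 764, 765, 766, 794, 796, 798]
      },
      "fixed": {
        "724": null, "726": null, "762": null, "764": "N", "765": null,
        "766": null, "794": null, "796": "E", "798": null
      }
    },
    {
      "name": "m3",
      "span": [807, 893],
      "gaps": [],
      "weights": {
        "medium": [[815, 822], [850, 857]],
        "heavy": [809, 851]
      },
      "fixed": {
        "851": null
      }
    }
  ]
}
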