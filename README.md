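# bridgeforge

Salt-bridge-guided comparative design of thermostable enzyme mutants, with
molecular-dynamics post-processing and Arrhenius kinetics utilities.

## The problem

Cold-adapted enzymes tend to be flexible and thermolabile; thermophilic
homologs are rigid but sluggish at low temperature.  One rational route out of
this activity–stability trade-off is to compare a cold-adapted target with
thermostable homologs of the same glycoside hydrolase family and graft in the
charged residues that let the homologs form extra salt bridges — ideally salt
bridge *networks* — near the termini, while leaving the catalytic pocket
flexible.  bridgeforge implements that pipeline for structural
bioinformaticians and protein engineers:

- **Salt-bridge detection** in PDB/mmCIF structures: an Asp/Glu carboxylate
  oxygen (OD1/OD2, OE1/OE2) within a cutoff (default 3.2 Å, the "strong
  bridge" convention) of a Lys/Arg/His side-chain nitrogen (NZ; NE/NH1/NH2;
  ND1/NE2).  One bridge per residue pair, reported as e.g. `D59–R156`.
  Published bridge tables in that notation can be parsed directly, so the
  analysis also runs without coordinates.
- **Networks and diffs**: connected components with ≥2 bridges; gained/lost
  bridges between a wild type and a mutant with mutation-aware position
  matching; preservation checks for wild-type networks.
- **Comparative design**: project every homolog's bridge residues onto the
  columns of a multiple sequence alignment; call *hotspots* (columns where ≥2
  homologs bridge but the target does not), derive *coordinating positions*
  (target positions that must supply the partner charge, e.g. a Lys that must
  become a bidentate Arg), and emit mutation proposals that copy the majority
  charge of the homologs.
- **Trajectory flexibility**: Kabsch superposition, per-frame RMSD, trailing-
  window per-residue Cα RMSF (default: final 40% of frames), and region-level
  classification of a mutant as rigidified/flexibilized per region.
- **Kinetics**: Arrhenius activation energy (`Ea = −slope·R` from ln v vs
  1/T), activity-curve normalization, and average peptide mass.

A fixtures module generates seeded synthetic structures with planted bridges,
trajectories with planted per-residue fluctuation amplitudes, and synthetic
rate tables, and packages a worked example — the published salt-bridge tables
of a cold-adapted exo-inulinase (InuAGN25, mature numbering from 23), three
thermophilic GH32 exo-inulinases (BfrA-Tm, Inu-Aa, InuA-Gs), the engineered
eight-site mutant Mut8S, and a synthetic stand-in alignment encoding their
published residue correspondences.

## Worked example

The packaged worked example runs the whole design loop from the published
bridge tables:

```
$ bridgeforge design --worked-example
{
  "schema": 1,
  "gained": [
    "D301–K243",
    "D59–R156",
    "E268–K244",
    "E61–R156"
  ],
  "lost": [],
  "proposals": [
    {
      "mutation": "N61E",
      "kind": "hotspot",
      "productive": true
    },
    {
      "mutation": "K156R",
      "kind": "coordinating",
      "productive": true
    },
    {
      "mutation": "P236E",
      "kind": "hotspot",
      "productive": false
    },
    {
      "mutation": "T243K",
      "kind": "coordinating",
      "productive": true
    },
    {
      "mutation": "D268E",
      "kind": "hotspot",
      "productive": true
    },
    {
      "mutation": "T277D",
      "kind": "hotspot",
      "productive": false
    },
    {
      "mutation": "Q390K",
      "kind": "coordinating",
      "productive": false
    },
    {
      "mutation": "R409D",
      "kind": "hotspot",
      "productive": false
    }
  ],
  "networks": [
    {
      "members": [
        "D453",
        "E458",
        "H41",
        "R331"
      ],
      "preserved": true
    },
    {
      "members": [
        "D176",
        "E230",
        "R178"
      ],
      "preserved": true
    }
  ]
}
```

Reading the output: hotspot calling on the alignment finds five columns where
two or three thermophilic homologs keep a bridge residue and the target does
not (target positions 61, 236, 268, 277, 409), plus three coordinating
partner positions (156, 243, 390) — eight proposals in total.  Against the
mutant's bridge table the design gains four bridges (`D59–R156` and
`E61–R156`, which form a new two-bridge N-terminal network through the
bidentate R156, plus `D301–K243` and `E268–K244`) and loses none;
"productive" marks proposals that touch at least one gained bridge.  Both
wild-type networks, including the three-bridge `D453–H41 / E458–H41 /
E458–R331` component, survive in the mutant.

Other subcommands: `bridges` (detect in a structure), `networks`, `diff`,
`hotspots`, `rmsf`, `flexcompare`, `arrhenius`, `fixtures`; see
`bridgeforge --help`.  The library API mirrors the CLI
(`bridgeforge.detect_bridges`, `design_mutations`, `rmsf_profile`,
`arrhenius_ea`, ...).

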