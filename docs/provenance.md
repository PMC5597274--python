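# Provenance of the bundled amino-acid index table

The package encodes tripeptides with 13 amino-acid indices known by their
descriptions and literature references.  The matching AAindex1 accessions
were resolved once against the public AAindex1 release (544 single-residue
entries) and frozen into `pepfocus.aaindex._BUNDLED_AAINDEX1`, so no
database is consulted at run time.

| # | Description | Accession | Primary reference |
|---|-------------|-----------|-------------------|
| 1 | Isoelectric point | ZIMJ680104 | Zimmerman, Eliezer & Simha, J. Theor. Biol. 21:170 (1968) |
| 2 | Normalized van der Waals volume | FAUJ880103 | Fauchere et al., Int. J. Peptide Protein Res. 32:269 (1988) |
| 3 | Alpha-helix indices for beta-proteins | GEIM800103 | Geisow & Roberts, Int. J. Biol. Macromol. 2:387 (1980) |
| 4 | Beta-strand indices for beta-proteins | GEIM800106 | Geisow & Roberts, Int. J. Biol. Macromol. 2:387 (1980) |
| 5 | Side-chain contribution to protein stability | TAKK010101 | Takano & Yutani, Protein Eng. 14:525 (2001) |
| 6 | Stability scale from the knowledge-based atom-atom potential | ZHOH040101 | Zhou & Zhou, Proteins 54:315 (2004) |
| 7 | Hydropathy index | KYTJ820101 | Kyte & Doolittle, J. Mol. Biol. 157:105 (1982) |
| 8 | Normalized frequency of turn | CRAJ730103 | Crawford, Lipscomb & Schellman, PNAS 70:538 (1973) |
| 9 | Free energy in beta-strand region | MUNV940104 | Munoz & Serrano, Proteins 20:301 (1994) |
| 10 | Free energy in alpha-helical region | MUNV940102 | Munoz & Serrano, Proteins 20:301 (1994) |
| 11 | Polarity | GRAR740102 | Grantham, Science 185:862 (1974) |
| 12 | Side chain interaction parameter | KRIW790101 | Krigbaum & Komoriya, Biochim. Biophys. Acta 576:204 (1979) |
| 13 | Amino acid distribution | JUKT750101 | Jukes, Holmquist & Moise, Science 189:50 (1975) |

## Ambiguous descriptions and the choices made

Several descriptions match more than one AAindex1 entry; the resolution
rules were:

* **Normalized frequency of turn** — CRAJ730103 is the only entry whose
  description matches verbatim; the Palau et al. (1981) variants all carry
  structural-class qualifiers.
* **Polarity** — both GRAR740102 (Grantham, 1974) and ZIMJ680103
  (Zimmerman et al., 1968) are titled "Polarity".  The table's isoelectric
  point already cites Zimmerman, while the polarity row cites a distinct
  reference, so the Grantham scale was chosen.
* **Side chain interaction parameter** — KRIW710101 (Krigbaum–Rubin, 1971)
  and KRIW790101 (Krigbaum–Komoriya, 1979) share the description; the later
  1979 revision was chosen.
* **Free energy in beta-strand region** — MUNV940104 and MUNV940105 share
  the description (two parameterizations from the same paper); MUNV940104,
  the first of the pair, was chosen.  The matching helical-region entry
  MUNV940102 was taken for index 10.
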