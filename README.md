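# grinmap

Residue-equivalence mapping and annotation transfer between the GluN1,
GluN2A and GluN2B subunits of the NMDA receptor.

## The problem

De novo missense variants in the *GRIN* genes (*GRIN1*, *GRIN2A*, *GRIN2B*)
cause *GRIN*-related neurodevelopmental disorders, but most reported
variants lack a pathogenicity call (pathogenic / benign) and almost all lack
a functional annotation (loss-of-function, gain-of-function, complex) — the
annotation that actually guides therapy choice.  The three subunits share a
conserved domain architecture: amino-terminal domain (ATD, two sublobes),
ligand-binding domain (LBD, the discontinuous S1+S2 segments), transmembrane
domain (TMD, M1–M3 plus M4) and a structurally unsolved C-terminal domain
(CTD).  Because the folds are conserved, a residue in one subunit has a
structurally *equivalent position* in the others, and a **homologous
variant** — the same amino-acid change at the equivalent position of another
subunit — is expected to perturb the receptor the same way.  `grinmap`
builds the equivalence maps and performs the transfer.

## The algorithm

1. **Per-domain superposition.**  For each subunit pair and domain, the
   alpha-carbon sets are superposed by a Kabsch least-squares fit
   (reflection-corrected, proper rotation) seeded from a sequence alignment,
   then refined by iterative outlier rejection: pairs with post-fit distance
   > 2.0 Å are discarded and the fit repeated (≤ 5 cycles).  The reported
   RMSD is over retained pairs,
   `RMSD = sqrt(Σᵢ ‖R xᵢ + t − yᵢ‖² / n)`.
2. **Structure-based alignment.**  After superposition, residues are paired
   by mutual-nearest-neighbour CA distance (≤ 4 Å) and pruned to the
   maximum non-crossing subset, giving an order-consistent residue
   alignment with per-domain identity statistics.
3. **Sequence fallback.**  Regions without coordinates (signal peptide,
   CTD, unresolved loops) are covered by Needleman–Wunsch global alignment
   (BLOSUM62, gap open 10 / extend 0.5), accepted only in runs of ≥ 5
   consecutive aligned columns.
4. **Equivalence map.**  Structural and fallback pairs are merged into a
   partial bijection of canonical positions per subunit pair (structural
   entries win), with three-way composition consistency checked and
   reported.
5. **Annotation transfer.**  For a query variant, homologs are database
   variants with the same reference *and* substituted residue at the
   equivalent position.  Unanimous confident annotations transfer;
   uncertain-significance annotations never transfer; disagreement yields an
   explicit conflict, not a call.
6. **Concordance evaluation.**  Variants at equivalent positions are
   compared in three categories — homologous (same initial, same final
   residue), same-final (different initials) and same-initial (different
   finals) — and the fraction of groups with coincident annotations is
   reported per category.

Canonical numbering throughout is 1-based over the full-length proteins,
signal peptide included, matching clinical HGVS `p.` notation (e.g. GluN2B
p.(Gly459Arg) ↔ GluN2A p.(Gly458Arg)).  Structures deposited with construct
or ortholog numbering are renumbered onto canonical coordinates via a
global sequence alignment.

## Worked example

Generate a self-contained synthetic workspace (two heterodimer structures,
canonical sequences, domain config, variant table), build the map, and
query positions:

```sh
grinmap fixtures demo_ws --seed 1
grinmap map --workspace demo_ws --save map.json \
    --query GluN2B:459 --query GluN1:685
```

```json
{
 "GluN2B:459": [
  {"subunit": "GluN1",  "pos": 457, "provenance": "structural"},
  {"subunit": "GluN2A", "pos": 458, "provenance": "structural"}
 ],
 "GluN1:685": [
  {"subunit": "GluN2A", "pos": 686, "provenance": "structural"},
  {"subunit": "GluN2B", "pos": 687, "provenance": "structural"}
 ]
}
```

GluN2B position 459 maps to GluN2A 458 (the one-residue canonical-numbering
offset between the two subunits), so GluN2B p.(Gly459Arg) and GluN2A
p.(Gly458Arg) are candidate homologs.  Transfer annotations across the
variant table:

```sh
grinmap annotate demo_ws/variants.tsv map.json \
    --out-predictions predictions.tsv --out-report expansion.json
head -3 predictions.tsv
```

```
gene    hgvs_p         status     predicted_pathogenicity  predicted_functional  supporting            provenance
GRIN1   p.(Lys685Arg)  no_homolog .                        .                     .                     inferred-by-homology
GRIN2A  p.(Gly458Arg)  predicted  pathogenic               LoF                   GRIN2B:p.(Gly459Arg)  inferred-by-homology
```

The nine unannotated GluN2A variants planted as homologs of pathogenic
GluN2B variants all receive a transferred `pathogenic` call
(`"predicted_pathogenic": 9` in `expansion.json`); the GluN1 Lys685Arg /
GluN2B Pro687Arg pair shares only the final residue, so nothing transfers.
`grinmap evaluate` and `grinmap table1` produce the concordance reports and
the per-domain identity/RMSD summary for the same workspace; `grinmap demo`
runs everything at once.

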