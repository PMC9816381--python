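"""End-to-end pipeline glue: workspace in, equivalence map and reports out.

A workspace directory (as written by ``fixtures.write_demo_workspace``, or
assembled by hand around real structure files) contains a manifest
(workspace.json) naming the structure files with their chain-to-subunit
assignments, a canonical-sequence FASTA, a domain-range config and a variant
table.  The pipeline reads the structures, reconciles construct numbering
with canonical numbering, superposes each subunit pair per domain, derives
the structural alignments, adds full-length sequence-alignment fallbacks for
unsolved regions, builds the trio equivalence map, and runs annotation
transfer and concordance evaluation over the variant table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from Bio import SeqIO

from . import alignment, equivalence, evaluate, structures, superposition, transfer, variants
from .alignment import ResidueAlignment, derive_structural_alignment, global_align
from .equivalence import EquivalenceMap, build_map
from .structures import ChainModel, NumberingMap, ResidueSite, extract_domain
from .superposition import iterative_superpose

SUBUNIT_PAIRS = (("GluN1", "GluN2A"), ("GluN1", "GluN2B"), ("GluN2A", "GluN2B"))


def read_fasta_sequences(path: str | Path) -> dict[str, str]:
    """Subunit -> sequence from a FASTA whose record ids name the subunits
    (GluN1/GluN2A/GluN2B or the GRIN gene symbols)."""
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id.split("|")[0]
        subunit = structures.GENE_TO_SUBUNIT.get(name.upper(), name)
        if subunit in structures.SUBUNITS:
            out[subunit] = str(rec.seq).upper()
    return out


@dataclass
class Workspace:
    directory: Path
    chains: dict[str, ChainModel]
    sequences: dict[str, str]
    domains: dict[str, dict[str, structures.DomainDefinition]]
    variants_path: Path | None = None

    @classmethod
    def load(cls, directory: str | Path) -> "Workspace":
        directory = Path(directory)
        manifest = json.loads((directory / "workspace.json").read_text())
        sequences = read_fasta_sequences(directory / manifest["sequences"])
        domains = structures.load_domain_config(directory / manifest["domains"])
        chains: dict[str, ChainModel] = {}
        for entry in manifest["structures"]:
            chain_map = entry["chains"]
            models = structures.read_structure(
                directory / entry["path"], subunit_of_chain=chain_map
            )
            numbering = entry.get("numbering", "canonical")
            for cm in models:
                name = cm.source.rsplit(":", 1)[-1]
                needs_renumber = isinstance(numbering, dict) and name in numbering
                if needs_renumber:
                    cm = renumber_to_canonical(cm, sequences[cm.subunit])
                # first protomer of each subunit wins (chain-selection default)
                chains.setdefault(cm.subunit, cm)
        vpath = directory / manifest["variants"] if "variants" in manifest else None
        return cls(directory, chains, sequences, domains, vpath)


def renumber_to_canonical(chain: ChainModel, canonical_seq: str) -> ChainModel:
    """Rewrite a deposited-construct chain onto canonical numbering via a
    global alignment of the construct sequence against the canonical
    sequence.  Mismatched residues stay mapped (they are alignment columns),
    mirroring how a near-identical ortholog construct is reconciled."""
    aln = global_align(
        chain.sequence,
        canonical_seq,
        positions_a=chain.positions,
    )
    mapping = NumberingMap.from_alignment(aln)
    return structures.renumber(chain, mapping, strict=False)


def build_equivalence(
    ws: Workspace,
    cycles: int = 5,
    reject_cutoff: float = 2.0,
    pairing_cutoff: float = 4.0,
    min_fallback_run: int = 5,
) -> EquivalenceMap:
    """Build the trio equivalence map from a workspace.

    Per subunit pair and domain (ATD sublobes separately): extract, seed with
    a sequence alignment of the structured residues, superpose with outlier
    rejection, read off the structural alignment.  A full-length global
    sequence alignment per pair supplies fallback pairs for positions without
    structural coverage (signal peptide, CTD, unresolved loops)."""
    domain_alignments: list[ResidueAlignment] = []
    fallbacks: list[ResidueAlignment] = []
    for sub_a, sub_b in SUBUNIT_PAIRS:
        if sub_a not in ws.chains or sub_b not in ws.chains:
            continue
        for part in ("ATD1", "ATD2", "LBD", "TMD"):
            dom_a = ws.domains[sub_a][part]
            dom_b = ws.domains[sub_b][part]
            a = extract_domain(ws.chains[sub_a], dom_a)
            b = extract_domain(ws.chains[sub_b], dom_b)
            a = ChainModel(a.subunit, a.structured_residues(), a.source)
            b = ChainModel(b.subunit, b.structured_residues(), b.source)
            seed = global_align(
                a.sequence,
                b.sequence,
                positions_a=a.positions,
                positions_b=b.positions,
                subunit_pair=(sub_a, sub_b),
                domain=part,
            )
            sup = iterative_superpose(a, b, seed, cycles, reject_cutoff)
            if sup.rmsd > reject_cutoff:
                # the fit never converged below the rejection cutoff: the seed
                # register is unreliable, so no structural pairs are claimed
                # for this domain (sequence fallback may still cover it)
                warnings.warn(
                    f"superposition of {sub_a}/{sub_b} {part} did not converge "
                    f"(rmsd {sup.rmsd:.2f} Å); structural pairing skipped"
                )
                continue
            moved = ChainModel(
                a.subunit,
                [
                    ResidueSite(r.subunit, r.pos, r.aa, tuple(sup.apply(r.ca_array)))
                    for r in a.residues
                ],
                a.source,
            )
            domain_alignments.append(
                derive_structural_alignment(
                    moved, b, pairing_cutoff, subunit_pair=(sub_a, sub_b), domain=part
                )
            )
        fallbacks.append(
            global_align(
                ws.sequences[sub_a],
                ws.sequences[sub_b],
                subunit_pair=(sub_a, sub_b),
            )
        )
    return build_map(domain_alignments, fallbacks, min_fallback_run=min_fallback_run)


def run_demo(directory: str | Path, emap: EquivalenceMap | None = None) -> dict:
    """Full pipeline over a workspace; returns a JSON-serialisable summary.

    Covers: equivalence map size and three-way consistency, the per-domain
    identity/RMSD table, annotation-transfer predictions with the expansion
    report, and concordance reports for the three comparison categories."""
    ws = Workspace.load(directory)
    if emap is None:
        emap = build_equivalence(ws)
    db = variants.read_variant_table(ws.variants_path)

    mismatches = variants.validate_against_sequence(db, ws.sequences)
    predictions, expansion = transfer.annotate_database(db, emap)
    table1 = evaluate.summarize_table1(ws.chains, ws.domains)

    reports = {}
    for category in evaluate.ComparisonCategory:
        groups = evaluate.group_equivalent_variants(db, emap, category)
        reports[category.value] = {
            kind: evaluate.concordance(groups, db, kind).to_dict()
            for kind in ("pathogenicity", "functional")
        }

    n_pairs = {f"{a}-{b}": len(emap.pairs(a, b)) for a, b in SUBUNIT_PAIRS}
    return {
        "map_pair_counts": n_pairs,
        "three_way_inconsistencies": len(equivalence.check_three_way_consistency(emap)),
        "sequence_mismatches": [str(v) for v, _ in mismatches],
        "table1": table1.to_dict(orient="records"),
        "n_predictions": len(predictions),
        "expansion": expansion.to_dict(),
        "concordance": reports,
        "predictions": transfer.predictions_frame(predictions).to_dict(orient="records"),
    }
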