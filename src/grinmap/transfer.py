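"""Annotation transfer between homologous GluN variants.

A homolog of a variant is a database variant in another subunit carrying the
same amino-acid change (same reference and same substituted residue) at the
structurally equivalent position.  Pathogenicity and functional annotations
of homologs are extrapolated to the query variant; uncertain or unannotated
homolog values never transfer, and disagreeing homologs produce an explicit
conflict instead of a call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

import pandas as pd

from .equivalence import EquivalenceMap
from .variants import (
    AnnotationRecord,
    Functional,
    Pathogenicity,
    ProteinVariant,
    VariantDatabase,
)


class PredictionStatus(str, Enum):
    PREDICTED = "predicted"
    NO_HOMOLOG = "no_homolog"
    HOMOLOG_UNANNOTATED = "homolog_unannotated"
    CONFLICT = "conflict"


@dataclass
class Prediction:
    target: ProteinVariant
    status: PredictionStatus
    predicted_pathogenicity: Pathogenicity | None = None
    predicted_functional: Functional | None = None
    supporting: list[tuple[ProteinVariant, AnnotationRecord]] = field(default_factory=list)


def find_homologs(
    v: ProteinVariant, emap: EquivalenceMap, db: VariantDatabase
) -> list[ProteinVariant]:
    """Database variants homologous to ``v``: same ref and alt residues at an
    equivalent position of another subunit.  Variants at equivalent positions
    with a different initial or final residue are not homologs and are
    excluded."""
    out = []
    for partner, pos, _prov in sorted(emap.map_position(v.subunit, v.pos)):
        candidate = None
        try:
            candidate = ProteinVariant(partner, pos, v.ref, v.alt)
        except ValueError:
            continue
        if candidate in db:
            out.append(candidate)
    return out


def _transferred_class(values: list):
    """Unanimous informative value, None (nothing informative) or 'conflict'."""
    distinct = set(values)
    if not distinct:
        return None
    if len(distinct) == 1:
        return distinct.pop()
    return "conflict"


def predict(v: ProteinVariant, emap: EquivalenceMap, db: VariantDatabase) -> Prediction:
    """Extrapolate annotations to ``v`` from its annotated homologs.

    Pathogenicity and functional classes transfer independently; a homolog
    may support one and not the other.  Uncertain pathogenicity is never
    transferred (and never causes a conflict).
    """
    homologs = find_homologs(v, emap, db)
    supporting = [(h, db.annotation(h)) for h in homologs]
    if not homologs:
        return Prediction(v, PredictionStatus.NO_HOMOLOG, supporting=supporting)

    path_values = [
        rec.pathogenicity
        for _, rec in supporting
        if rec.pathogenicity not in (Pathogenicity.UNCERTAIN, Pathogenicity.UNANNOTATED)
    ]
    func_values = [
        rec.functional for _, rec in supporting if rec.functional != Functional.UNANNOTATED
    ]
    path_call = _transferred_class(path_values)
    func_call = _transferred_class(func_values)

    if path_call == "conflict" or func_call == "conflict":
        status = PredictionStatus.CONFLICT
        path_call = None if path_call == "conflict" else path_call
        func_call = None if func_call == "conflict" else func_call
    elif path_call is None and func_call is None:
        status = PredictionStatus.HOMOLOG_UNANNOTATED
    else:
        status = PredictionStatus.PREDICTED
    return Prediction(v, status, path_call, func_call, supporting)


@dataclass
class ExpansionReport:
    """How far homology transfer expands the annotated variant repertoire."""

    n_variants: int
    baseline_pathogenic: int
    baseline_uncertain: int
    baseline_functional: int
    predicted_pathogenic: int
    predicted_benign: int
    vus_resolved: int
    functional_predicted_by_subunit: dict[str, int]
    conflicts: int

    @property
    def functional_predicted(self) -> int:
        return sum(self.functional_predicted_by_subunit.values())

    @property
    def pathogenic_increase_percent(self) -> float:
        if self.baseline_pathogenic == 0:
            return float("nan")
        return 100.0 * self.predicted_pathogenic / self.baseline_pathogenic

    @property
    def vus_decrease_percent(self) -> float:
        if self.baseline_uncertain == 0:
            return float("nan")
        return 100.0 * self.vus_resolved / self.baseline_uncertain

    @property
    def functional_increase_percent(self) -> float:
        if self.baseline_functional == 0:
            return float("nan")
        return 100.0 * self.functional_predicted / self.baseline_functional

    def to_dict(self) -> dict:
        def _finite(x):
            return x if x == x and abs(x) != float("inf") else None

        return {
            "n_variants": self.n_variants,
            "baseline_pathogenic": self.baseline_pathogenic,
            "baseline_uncertain": self.baseline_uncertain,
            "baseline_functional": self.baseline_functional,
            "predicted_pathogenic": self.predicted_pathogenic,
            "predicted_benign": self.predicted_benign,
            "vus_resolved": self.vus_resolved,
            "functional_predicted_by_subunit": dict(self.functional_predicted_by_subunit),
            "functional_predicted": self.functional_predicted,
            "conflicts": self.conflicts,
            "pathogenic_increase_percent": _finite(self.pathogenic_increase_percent),
            "vus_decrease_percent": _finite(self.vus_decrease_percent),
            "functional_increase_percent": _finite(self.functional_increase_percent),
        }


def annotate_database(
    db: VariantDatabase, emap: EquivalenceMap
) -> tuple[list[Prediction], ExpansionReport]:
    """Run annotation transfer over every variant lacking a confident
    annotation in at least one dimension (pathogenicity uncertain/unannotated,
    or functional unannotated).

    Predictions are returned as a separate collection — observed annotations
    are never overwritten — together with an ExpansionReport counting the
    newly predicted pathogenic variants, resolved uncertain-significance
    variants and new functional annotations, with percent changes relative to
    the annotated baseline of the input database."""
    predictions: list[Prediction] = []
    predicted_pathogenic = predicted_benign = vus_resolved = conflicts = 0
    functional_by_subunit: dict[str, int] = {}

    baseline_pathogenic = baseline_uncertain = baseline_functional = 0
    for v, rec in db.items():
        if rec.pathogenicity == Pathogenicity.PATHOGENIC:
            baseline_pathogenic += 1
        elif rec.pathogenicity == Pathogenicity.UNCERTAIN:
            baseline_uncertain += 1
        if rec.functional != Functional.UNANNOTATED:
            baseline_functional += 1

    for v, rec in db.items():
        needs_path = rec.pathogenicity in (
            Pathogenicity.UNCERTAIN,
            Pathogenicity.UNANNOTATED,
        )
        needs_func = rec.functional == Functional.UNANNOTATED
        if not needs_path and not needs_func:
            continue
        p = predict(v, emap, db)
        if not needs_path:
            p.predicted_pathogenicity = None
        if not needs_func:
            p.predicted_functional = None
        predictions.append(p)
        if p.status == PredictionStatus.CONFLICT:
            conflicts += 1
        if p.predicted_pathogenicity == Pathogenicity.PATHOGENIC:
            predicted_pathogenic += 1
        elif p.predicted_pathogenicity == Pathogenicity.BENIGN:
            predicted_benign += 1
        if p.predicted_pathogenicity is not None and rec.pathogenicity == Pathogenicity.UNCERTAIN:
            vus_resolved += 1
        if p.predicted_functional is not None:
            functional_by_subunit[v.subunit] = functional_by_subunit.get(v.subunit, 0) + 1

    report = ExpansionReport(
        n_variants=len(db),
        baseline_pathogenic=baseline_pathogenic,
        baseline_uncertain=baseline_uncertain,
        baseline_functional=baseline_functional,
        predicted_pathogenic=predicted_pathogenic,
        predicted_benign=predicted_benign,
        vus_resolved=vus_resolved,
        functional_predicted_by_subunit=functional_by_subunit,
        conflicts=conflicts,
    )
    return predictions, report


def predictions_frame(predictions: Iterable[Prediction]) -> pd.DataFrame:
    """Tabular view of predictions with an explicit provenance column
    ('inferred-by-homology') so they are never mistaken for observations."""
    rows = []
    for p in predictions:
        rows.append(
            {
                "gene": p.target.gene,
                "hgvs_p": p.target.hgvs_p(),
                "status": p.status.value,
                "predicted_pathogenicity": p.predicted_pathogenicity.value
                if p.predicted_pathogenicity
                else ".",
                "predicted_functional": p.predicted_functional.value
                if p.predicted_functional
                else ".",
                "supporting": ";".join(f"{h.gene}:{h.hgvs_p()}" for h, _ in p.supporting) or ".",
                "provenance": "inferred-by-homology",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "hgvs_p",
            "status",
            "predicted_pathogenicity",
            "predicted_functional",
            "supporting",
            "provenance",
        ],
    )
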