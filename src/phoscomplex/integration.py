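"""Phosphosite x interactor association matrix and mutant-based classification.

An *association* is the co-migration of an interactor with a bait phosphosite
in at least one module.  Each association is then classified against the
AP-MS differential result of the matching phosphosite-null (Ser/Thr -> Ala)
mutant versus wild type:

* ``phospho_required``   — binding lost in the null mutant (log2FC < -1, P < 0.05)
* ``phospho_inhibitory`` — binding gained in the null mutant (log2FC > +1, P < 0.05)
* ``unaffected``         — no threshold crossed
* ``untested``           — no single-site mutant exists for the phosphosite

Inequalities are strict on both the fold-change and the P-value thresholds.
Multi-site mutants are excluded from single-site classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .comigration import Module
from .config import IntegrationParams

CLASSES = ("phospho_required", "phospho_inhibitory", "unaffected", "untested")


@dataclass(frozen=True)
class Association:
    interactor: str
    phosphosite: str
    modules: tuple[str, ...] = field(default=())


def comigration_associations(modules: list[Module]) -> list[Association]:
    """All (interactor, phosphosite) pairs sharing at least one module."""
    pair_modules: dict[tuple[str, str], list[str]] = {}
    for m in modules:
        for interactor in m.members:
            for site in m.phosphosignature:
                pair_modules.setdefault((interactor, site), []).append(m.module_id)
    return [Association(i, s, tuple(mods))
            for (i, s), mods in sorted(pair_modules.items())]


def classify_association(assoc: Association,
                         mutant_results: dict[str, pd.DataFrame],
                         params: IntegrationParams | None = None) -> str:
    """Class of one association given per-site mutant differential tables.

    ``mutant_results`` maps a phosphosite (e.g. ``"S367"``) to the
    differential table of its alanine mutant vs wild type (columns
    ``protein``, ``log2fc``, ``p`` and, optionally, ``q``).
    """
    params = params or IntegrationParams()
    table = mutant_results.get(assoc.phosphosite)
    if table is None:
        return "untested"
    row = table[table["protein"] == assoc.interactor]
    if row.empty:
        return "untested"
    lfc = float(row["log2fc"].iloc[0])
    p = float(row["q" if params.use_q else "p"].iloc[0])
    if lfc < params.fc_down and p < params.p_max:
        return "phospho_required"
    if lfc > params.fc_up and p < params.p_max:
        return "phospho_inhibitory"
    return "unaffected"


def association_matrix(modules: list[Module],
                       mutant_results: dict[str, pd.DataFrame],
                       params: IntegrationParams | None = None) -> pd.DataFrame:
    """Long-form association matrix: one row per co-migrating pair with class."""
    params = params or IntegrationParams()
    rows = []
    for assoc in comigration_associations(modules):
        rows.append({
            "interactor": assoc.interactor,
            "phosphosite": assoc.phosphosite,
            "modules": ";".join(assoc.modules),
            "n_modules": len(assoc.modules),
            "class": classify_association(assoc, mutant_results, params),
        })
    return pd.DataFrame(rows, columns=["interactor", "phosphosite", "modules",
                                       "n_modules", "class"])


def class_counts(matrix: pd.DataFrame) -> dict[str, int]:
    counts = {c: 0 for c in CLASSES}
    if not matrix.empty:
        counts.update(matrix["class"].value_counts().to_dict())
    counts["total"] = 0 if matrix.empty else len(matrix)
    return counts
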