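"""Module plausibility checks.

Two orthogonal lines of evidence that co-migration modules are physical
assemblies rather than coincidence: (i) within-module protein pairs are
recovered from a reference interaction network (BioGRID-style edge list)
more often than arbitrary pairs of the bait's interactors; (ii) modules are
enriched for specific cellular-compartment annotation terms under an
upper-tail hypergeometric test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .comigration import Module
from .errors import ValidationError

log = logging.getLogger(__name__)


def pair_recall(members: list[str], reference: set[frozenset]) -> float:
    """Fraction of unordered within-member pairs present in the reference."""
    pairs = list(combinations(sorted(set(members)), 2))
    if not pairs:
        raise ValidationError("recall undefined for fewer than 2 members")
    hits = sum(frozenset(p) in reference for p in pairs)
    return hits / len(pairs)


@dataclass
class RecallComparison:
    module_recalls: dict[str, float]
    background_recall: float          # over all pairs of the interactor universe
    background_samples: list[float] = field(default_factory=list)
    shapiro_p: float = float("nan")
    comparison_p: float = float("nan")


def recall_vs_background(modules: list[Module], reference: set[frozenset],
                         universe: set[str], bait_id: str = "BAIT",
                         n_resamples: int = 200, seed: int = 0) -> RecallComparison:
    """Per-module reference recall versus the all-pairs interactor background.

    The universe is the bait's interactor set excluding the bait itself.  The
    background distribution is built by resampling, for each module, random
    member sets of the same size from the universe and computing their
    recall; a two-sided unpaired t-test compares module recalls against these
    samples, and Shapiro-Wilk assays the module-recall distribution for
    normality.  Single-member modules are excluded with a warning.
    """
    universe = set(universe) - {bait_id}
    rng = np.random.default_rng(seed)
    recalls: dict[str, float] = {}
    sizes: list[int] = []
    for m in modules:
        members = [p for p in m.members if p != bait_id]
        if len(set(members)) < 2:
            log.warning("recall: module %s has <2 members; excluded", m.module_id)
            continue
        recalls[m.module_id] = pair_recall(members, reference)
        sizes.append(len(set(members)))
    if not recalls:
        raise ValidationError("no module with >= 2 members")
    background = pair_recall(sorted(universe), reference) if len(universe) >= 2 else 0.0

    pool = sorted(universe)
    samples: list[float] = []
    for size in sizes:
        size = min(size, len(pool))
        for _ in range(n_resamples):
            subset = rng.choice(pool, size=size, replace=False)
            samples.append(pair_recall(list(subset), reference))

    mod_vals = np.array(list(recalls.values()))
    bg_vals = np.array(samples)
    shapiro_p = float(stats.shapiro(mod_vals).pvalue) if len(mod_vals) >= 3 else float("nan")
    if np.allclose(mod_vals.std(), 0) and np.allclose(bg_vals.std(), 0) \
            and np.isclose(mod_vals.mean(), bg_vals.mean()):
        comparison_p = 1.0
    else:
        comparison_p = float(stats.ttest_ind(mod_vals, bg_vals, equal_var=False).pvalue)
    return RecallComparison(recalls, background, samples, shapiro_p, comparison_p)


def term_enrichment(module_members: list[str], annotation: dict[str, set[str]],
                    term: str, universe: set[str],
                    alpha: float = 0.05) -> tuple[float, bool]:
    """Upper-tail hypergeometric P(X >= k) for one term in one module.

    Population N = |universe|, successes K = |term members in universe|,
    draws n = |module|, observed k.  Returns (p, significant at ``alpha``).
    """
    if term not in annotation:
        raise ValidationError(f"term {term!r} absent from annotation")
    members = set(module_members) & universe
    term_set = annotation[term] & universe
    n_pop, n_succ, n_draw = len(universe), len(term_set), len(members)
    k = len(members & term_set)
    p = float(stats.hypergeom.sf(k - 1, n_pop, n_succ, n_draw))
    return p, p < alpha


def enrichment_table(modules: list[Module], annotation: dict[str, set[str]],
                     universe: set[str], alpha: float = 0.05):
    """Hypergeometric p per (module, term); no multiple-testing correction."""
    import pandas as pd

    rows = []
    for m in modules:
        if len(m.members) < 1:
            continue
        for term in annotation:
            p, sig = term_enrichment(m.members, annotation, term, universe, alpha)
            rows.append({"module": m.module_id, "term": term, "p": p, "significant": sig})
    return pd.DataFrame(rows)
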