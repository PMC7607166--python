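"""Three-source directional-consistency calls and candidate ranking.

A SNP-gene pair is nominated when three independent observations agree for
every evaluable pairwise race comparison: (i) the gene's DE direction
between the two races, (ii) the eQTL effect direction of the SNP, and
(iii) the ordering of the effect-allele frequency between the same two
races.  Working on the *effect-allele* (expression-increasing) frequency
folds (ii) into the orientation, so the per-comparison rule reduces to
sign(f_group - f_reference) == DE direction.

Comparisons where the gene is not differentially expressed are skipped
rather than counted against the pair (the reported tables include NDE cells
among nominated genes); a minimum frequency gap guards against calling a
direction on sampling noise.  The verdict requires unanimity across the
evaluated comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from raceqtl.errors import ConfigError
from raceqtl.de import STANDARD_COMPARISONS

DEFAULT_MIN_GAP = 0.02

_DIR_CODE = {"up": 1, "down": -1, "nde": 0}


@dataclass
class DirectionVector:
    """Per-comparison DE direction for one gene: +1 up, -1 down, 0 NDE."""

    gene_id: str
    directions: dict[tuple[str, str], int]


@dataclass
class ConsistencyCall:
    """Per-comparison agreement and the overall verdict for one SNP-gene pair.

    verdict is 'consistent' iff at least one comparison was evaluated and
    every evaluated comparison agreed; 'unevaluable' iff none could be
    evaluated (all NDE or sub-gap); otherwise 'inconsistent'.
    """

    snp_id: str
    gene_id: str
    status: dict[tuple[str, str], str] = field(default_factory=dict)

    @property
    def n_evaluated(self) -> int:
        return sum(s in ("consistent", "inconsistent") for s in self.status.values())

    @property
    def n_consistent(self) -> int:
        return sum(s == "consistent" for s in self.status.values())

    @property
    def verdict(self) -> str:
        if self.n_evaluated == 0:
            return "unevaluable"
        return "consistent" if self.n_consistent == self.n_evaluated else "inconsistent"


def build_direction_vector(
    gene_id: str, de_tables: dict[tuple[str, str], pd.DataFrame]
) -> DirectionVector:
    """Collect the gene's DE directions across the three comparisons.

    A gene absent from a comparison's table counts as NDE there.
    """
    directions = {}
    for comp, table in de_tables.items():
        if gene_id in table.index:
            directions[comp] = _DIR_CODE[str(table.loc[gene_id, "direction"])]
        else:
            directions[comp] = 0
    return DirectionVector(gene_id=gene_id, directions=directions)


def check_consistency(
    dv: DirectionVector,
    increasing_allele_freqs: dict[str, float],
    min_gap: float = DEFAULT_MIN_GAP,
    snp_id: str = "snp",
) -> ConsistencyCall:
    """Compare DE direction with effect-allele frequency ordering per comparison.

    For comparison (A vs B) with DE direction d != 0 the status is
    'consistent' iff sign(f_A - f_B) == d and |f_A - f_B| >= min_gap;
    'skipped_small_gap' when the gap is below min_gap; 'skipped_nde' when
    d == 0.
    """
    if min_gap < 0:
        raise ConfigError("min_gap must be >= 0")
    for f in increasing_allele_freqs.values():
        if not 0.0 <= f <= 1.0:
            raise ConfigError("effect-allele frequencies must lie in [0, 1]")
    call = ConsistencyCall(snp_id=snp_id, gene_id=dv.gene_id)
    for (group, ref), d in dv.directions.items():
        if group not in increasing_allele_freqs or ref not in increasing_allele_freqs:
            raise ConfigError(f"population missing from frequencies for {group} vs {ref}")
        if d == 0:
            call.status[(group, ref)] = "skipped_nde"
            continue
        gap = increasing_allele_freqs[group] - increasing_allele_freqs[ref]
        if abs(gap) < min_gap:
            call.status[(group, ref)] = "skipped_small_gap"
        elif int(np.sign(gap)) == d:
            call.status[(group, ref)] = "consistent"
        else:
            call.status[(group, ref)] = "inconsistent"
    return call


def rank_candidates(
    calls: list[ConsistencyCall],
    survival_results: pd.DataFrame,
    de_tables: dict[tuple[str, str], pd.DataFrame],
    alpha: float = 0.05,
) -> dict:
    """Deterministic candidate table: consistent SNP support + significant survival.

    Candidates are sorted by (n_consistent desc, survival p asc,
    max |log2fc| desc, gene_id) — an explicit total order so runs are
    reproducible.  Pairs that are consistent but survival-null are retained
    in a secondary 'consistent_only' listing.
    """
    rows, consistent_only = [], []
    for call in calls:
        if call.verdict != "consistent":
            continue
        max_lfc = max(
            (
                abs(float(t.loc[call.gene_id, "log2fc"]))
                for t in de_tables.values()
                if call.gene_id in t.index
            ),
            default=0.0,
        )
        if call.gene_id in survival_results.index:
            surv_p = float(survival_results.loc[call.gene_id, "p"])
            surv_padj = float(survival_results.loc[call.gene_id, "padj"])
        else:
            surv_p, surv_padj = np.nan, np.nan
        entry = {
            "snp_id": call.snp_id,
            "gene_id": call.gene_id,
            "n_consistent": call.n_consistent,
            "n_evaluated": call.n_evaluated,
            "survival_p": surv_p,
            "survival_padj": surv_padj,
            "max_abs_log2fc": max_lfc,
            **{
                f"status_{g}_vs_{r}": s for (g, r), s in sorted(call.status.items())
            },
        }
        if np.isfinite(surv_padj) and surv_padj <= alpha:
            rows.append(entry)
        else:
            consistent_only.append(entry)

    def _key(e):
        return (-e["n_consistent"], e["survival_p"], -e["max_abs_log2fc"], e["gene_id"])

    rows.sort(key=_key)
    for i, e in enumerate(rows, 1):
        e["rank"] = i
    return {
        "candidates": pd.DataFrame(rows),
        "consistent_only": pd.DataFrame(consistent_only),
    }


def select_recurrent_families(
    deg_sets: dict[tuple[str, tuple[str, str]], set[tuple[str, str]]],
    family_map: dict[str, str],
) -> pd.DataFrame:
    """Flag gene families with recurrent same-direction DE evidence.

    ``deg_sets`` maps (cancer, comparison) to the set of (gene, direction)
    DEG calls.  A family passes condition 1 when some single
    (cancer, comparison) holds >= 2 members sharing a direction, and
    condition 2 when members are DE with a shared direction in >= 2 distinct
    cancers; both are required for selection.  "Similar differential
    expression patterns" is operationalized as same-sign DEG status in the
    same comparison.
    """
    per_family: dict[str, dict] = {}
    for (cancer, comparison), degs in deg_sets.items():
        for gene, direction in degs:
            fam = family_map.get(gene)
            if fam is None:
                continue
            rec = per_family.setdefault(fam, {"members": set(), "evidence": []})
            rec["members"].add(gene)
            rec["evidence"].append((cancer, comparison, gene, direction))
    rows = []
    for fam, rec in sorted(per_family.items()):
        ev = pd.DataFrame(
            rec["evidence"], columns=["cancer", "comparison", "gene", "direction"]
        )
        # condition 1: one (cancer, comparison) cell with >=2 members, same direction
        cell_counts = ev.groupby(["cancer", "comparison", "direction"])["gene"].nunique()
        cond1 = bool((cell_counts >= 2).any())
        # condition 2: same-direction DE membership in >= 2 distinct cancers
        cancers_per_dir = ev.groupby("direction")["cancer"].nunique()
        cond2 = bool((cancers_per_dir >= 2).any())
        rows.append(
            {
                "family": fam,
                "members": ",".join(sorted(rec["members"])),
                "n_members_de": len(rec["members"]),
                "n_cancers": int(ev["cancer"].nunique()),
                "condition1": cond1,
                "condition2": cond2,
                "selected": cond1 and cond2,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "family", "members", "n_members_de", "n_cancers",
            "condition1", "condition2", "selected",
        ],
    )


def manhattan_table(
    calls: list[ConsistencyCall], genotypes, eqtl_frame: pd.DataFrame
) -> pd.DataFrame:
    """Manhattan-plot-ready export (snp, chrom, pos, p); rendering is out of scope."""
    rows = []
    pmap = (
        eqtl_frame.set_index(["snp_id", "gene_id"])["p"].to_dict()
        if len(eqtl_frame)
        else {}
    )
    for call in calls:
        if call.snp_id in genotypes.dosages.index:
            rows.append(
                {
                    "snp_id": call.snp_id,
                    "chrom": genotypes.chrom[call.snp_id],
                    "pos": int(genotypes.pos[call.snp_id]),
                    "p": float(pmap.get((call.snp_id, call.gene_id), np.nan)),
                    "verdict": call.verdict,
                }
            )
    return pd.DataFrame(rows)


def standard_directions(dv: DirectionVector) -> tuple[int, int, int]:
    """The (AS vs CA, AS vs AA, AA vs CA) direction triple."""
    return tuple(dv.directions[c] for c in STANDARD_COMPARISONS)
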