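"""Vernalization-response and growth-habit classification, top-fraction
selection, clade summaries, augmented-design check adjustment, and
candidate-gene retrieval around significant markers.

The classification rules are explicit day-count and allele-call decision
tables used for barley winter/facultative/spring growth habit:

* Vernalization response from days to flowering (DTF) of unvernalized
  plants: insensitive (DTF <= 73), intermediate (74-129), sensitive
  (>= 130); the assay is censored at 154 days.
* VRN-H2 locus status from the presence of its three ZCCT-H genes:
  complete deletion (all three absent), intact (all present), otherwise a
  partial deletion.
* Facultative growth habit requires the full genetic key: complete
  VRN-H2 deletion, the winter VRN-H1 allele (intact intron 1), the
  short-day-sensitive (truncated HvFT3) PPD-H2 allele, and no
  vernalization requirement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GeneAnnotation


@dataclass(frozen=True)
class VernClassConfig:
    insensitive_max: int = 73
    sensitive_min: int = 130
    censor: int = 154

    def __post_init__(self) -> None:
        if not self.insensitive_max < self.sensitive_min <= self.censor:
            raise ValueError("need insensitive_max < sensitive_min <= censor")


@dataclass(frozen=True)
class LocusCallSet:
    """Categorical allele calls at the four growth-habit loci.

    ``vrn_h2_status`` is derivable from the three ZCCT gene flags when
    they are known (:func:`call_vrn_h2`); for assays that report only a
    locus-level "partial deletion" it may be set directly.
    """

    accession: str
    ppd_h2: str | None  # intact_HvFT3 | truncated_HvFT3 | novel_deletion | None
    ppd_h1: str | None  # dominant_PPD-H1 | recessive_ppd-H1 | None
    vrn_h1: str | None  # intact_intron1 | other | None
    vrn_h2_status: str | None  # intact | partial_deletion | complete_deletion


def classify_vernalization(dtf, cfg: VernClassConfig = VernClassConfig()) -> str:
    """Vernalization class from DTF: insensitive / intermediate / sensitive.

    Censored observations carry the censor value and therefore classify as
    sensitive.  Missing DTF returns ``"unclassified"``.
    """
    if dtf is None or (isinstance(dtf, float) and math.isnan(dtf)):
        return "unclassified"
    dtf = int(dtf)
    if dtf < 1:
        raise ValueError("DTF must be >= 1")
    if dtf <= cfg.insensitive_max:
        return "insensitive"
    if dtf < cfg.sensitive_min:
        return "intermediate"
    return "sensitive"


def call_vrn_h2(ha_present, hb_present, hc_present) -> str:
    """VRN-H2 locus status from the presence of ZCCT-Ha/Hb/Hc.

    All three absent -> complete_deletion; all present -> intact; any
    other known combination -> partial_deletion; any missing flag ->
    missing.
    """
    flags = (ha_present, hb_present, hc_present)
    if any(f is None for f in flags):
        return "missing"
    if not any(flags):
        return "complete_deletion"
    if all(flags):
        return "intact"
    return "partial_deletion"


def classify_facultative(calls: LocusCallSet, vern_class: str) -> str:
    """Growth habit from locus calls and vernalization class.

    Decision table:

    * facultative -- complete VRN-H2 deletion AND intact-intron-1 VRN-H1
      AND truncated (short-day sensitive) HvFT3 AND vernalization
      insensitive: the full facultative genetic key.
    * winter -- intact VRN-H2 AND vernalization sensitive.
    * spring_like -- vernalization insensitive but missing part of the
      facultative key (no cold requirement, yet not the full ideotype).
    * unclassified -- everything else, including any missing field needed
      by the rules above.
    """
    if vern_class in (None, "unclassified"):
        return "unclassified"
    if (
        calls.vrn_h2_status == "complete_deletion"
        and calls.vrn_h1 == "intact_intron1"
        and calls.ppd_h2 == "truncated_HvFT3"
        and vern_class == "insensitive"
    ):
        return "facultative"
    if calls.vrn_h2_status == "intact" and vern_class == "sensitive":
        return "winter"
    if vern_class == "insensitive":
        if calls.vrn_h2_status is None or calls.ppd_h2 is None or calls.vrn_h1 is None:
            return "unclassified"
        return "spring_like"
    return "unclassified"


def parse_vrn_h2_label(label) -> tuple[str | None, tuple]:
    """Parse a printed VRN-H2 assay label into (status, ZCCT flags).

    Labels name the deleted genes (e.g. ``"Deletion ZCCT_Ha ZCCT_Hb"``),
    declare the locus ``"Intact ..."``, or report an unresolved
    ``"Partial deletion"`` whose per-gene flags stay unknown.
    """
    if label is None or (isinstance(label, float) and math.isnan(label)):
        return None, (None, None, None)
    text = str(label).strip()
    low = text.lower()
    if low.startswith("intact"):
        return "intact", (True, True, True)
    if low.startswith("partial"):
        return "partial_deletion", (None, None, None)
    if low.startswith("deletion"):
        flags = tuple(f"zcct_h{g}" not in low for g in "abc")
        return call_vrn_h2(*flags), flags
    raise ValueError(f"unrecognized VRN-H2 label {text!r}")


def locus_calls_from_table(df: pd.DataFrame) -> list[LocusCallSet]:
    """Build LocusCallSets from a KASP-style call table (columns: accession,
    ppd_h2, ppd_h1, vrn_h1, vrn_h2)."""
    out = []
    for _, row in df.iterrows():
        status, _ = parse_vrn_h2_label(row["vrn_h2"])
        out.append(
            LocusCallSet(
                accession=row["accession"],
                ppd_h2=None if pd.isna(row["ppd_h2"]) else row["ppd_h2"],
                ppd_h1=None if pd.isna(row["ppd_h1"]) else row["ppd_h1"],
                vrn_h1=None if pd.isna(row["vrn_h1"]) else row["vrn_h1"],
                vrn_h2_status=status,
            )
        )
    return out


# ---------------------------------------------------------------------------
# top-fraction selection and clade summaries
# ---------------------------------------------------------------------------


def select_top_fraction(
    mean_ws: pd.Series, frac: float = 0.05
) -> pd.Series:
    """The floor(frac * n) accessions with the highest mean WS.

    ``mean_ws`` is indexed by accession (typically
    :meth:`PhenotypeTable.mean_ws`).  Ties at the cutoff are broken by
    accession id (lexicographic), which keeps selection deterministic.
    """
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")
    mean_ws = mean_ws.dropna()
    n_top = int(np.floor(frac * len(mean_ws)))
    if n_top == 0:
        import warnings

        warnings.warn("top fraction rounds down to zero accessions")
        return mean_ws.iloc[0:0]
    df = mean_ws.rename("mean_ws").reset_index()
    df.columns = ["accession", "mean_ws"]
    df = df.sort_values(
        ["mean_ws", "accession"], ascending=[False, True], kind="mergesort"
    )
    top = df.head(n_top)
    return top.set_index("accession")["mean_ws"]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def clade_summary(
    membership: pd.Series, mean_ws: pd.Series
) -> tuple[pd.Series, int]:
    """Per-clade mean WS rounded half-up to integer, plus the grand mean.

    Half-up rounding matters: banker's rounding would differ on .5 values,
    and published clade averages use conventional rounding.  Empty clades
    are omitted.
    """
    joined = pd.DataFrame({"clade": membership, "ws": mean_ws}).dropna()
    means = joined.groupby("clade")["ws"].mean().map(_round_half_up)
    grand = _round_half_up(joined["ws"].mean())
    return means, grand


# ---------------------------------------------------------------------------
# augmented-design adjustment
# ---------------------------------------------------------------------------


@dataclass
class AugmentedLayout:
    """A Type II modified augmented design: unreplicated entries in blocks,
    each anchored by a replicated primary check and secondary checks.

    ``blocks`` maps block id -> {entry id -> value}; check entries appear
    in every block under the same id.
    """

    blocks: dict[str, dict[str, float]]
    primary_check: str
    secondary_checks: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for b, entries in self.blocks.items():
            if self.primary_check not in entries:
                raise ValueError(f"block {b!r} is missing the primary check")


@dataclass
class AdjustmentResult:
    adjusted: dict[str, float]  # entry id -> adjusted value (checks included)
    relative_efficiency: float
    method: str


def _check_variance(layout: AugmentedLayout, values, checks) -> float:
    """Pooled variance of replicated-check values around their check means."""
    devs = []
    for chk in checks:
        obs = [values[(b, chk)] for b in layout.blocks if chk in layout.blocks[b]]
        if len(obs) >= 2:
            obs = np.asarray(obs, dtype=float)
            devs.extend(obs - obs.mean())
    if not devs:
        return 0.0
    devs = np.asarray(devs)
    return float(devs @ devs / max(len(devs) - 1, 1))


def adjust_augmented(layout: AugmentedLayout, method: str = "primary") -> AdjustmentResult:
    """Check-based block adjustment with its relative efficiency.

    * ``none``: identity, RE = 1.
    * ``primary``: subtract each block's primary-check deviation from the
      grand primary-check mean (exact on additively block-shifted data).
    * ``secondary``: block correction from the regression of block check
      means (all checks) on the grand check mean -- a reconstruction of
      the secondary-check adjustment for this design.

    Relative efficiency is the ratio of replicated-check variance before
    and after adjustment, evaluated on the checks not used to build the
    correction; RE <= 1 means the adjustment offers no advantage and raw
    values should be used.
    """
    raw = {
        (b, e): float(v) for b, entries in layout.blocks.items()
        for e, v in entries.items()
    }
    if method == "none":
        return AdjustmentResult(
            adjusted={e: v for (_, e), v in raw.items()},
            relative_efficiency=1.0,
            method="none",
        )

    blocks = list(layout.blocks)
    if method == "primary":
        chk = layout.primary_check
        grand = np.mean([layout.blocks[b][chk] for b in blocks])
        correction = {b: layout.blocks[b][chk] - grand for b in blocks}
        eval_checks = layout.secondary_checks or (layout.primary_check,)
    elif method == "secondary":
        all_checks = (layout.primary_check, *layout.secondary_checks)
        block_means = {
            b: np.mean([layout.blocks[b][c] for c in all_checks
                        if c in layout.blocks[b]])
            for b in blocks
        }
        grand = np.mean(list(block_means.values()))
        correction = {b: block_means[b] - grand for b in blocks}
        eval_checks = (layout.primary_check,)
    else:
        raise ValueError(f"unknown adjustment method {method!r}")

    adjusted_cells = {(b, e): v - correction[b] for (b, e), v in raw.items()}
    var_before = _check_variance(layout, raw, eval_checks)
    var_after = _check_variance(layout, adjusted_cells, eval_checks)
    if var_after == 0.0:
        re = 1.0 if var_before == 0.0 else np.inf
    else:
        re = var_before / var_after
    return AdjustmentResult(
        adjusted={e: v for (_, e), v in adjusted_cells.items()},
        relative_efficiency=float(re),
        method=method,
    )


# ---------------------------------------------------------------------------
# candidate genes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CandidateGene:
    snp_id: str
    gene: GeneAnnotation
    distance: int  # 0 when the SNP lies inside the gene


def candidate_genes(
    significant_snps,
    annotations: list[GeneAnnotation],
    window_bp: int,
) -> dict[str, list[CandidateGene]]:
    """Genes overlapping each significant SNP or within ``window_bp`` of it.

    ``significant_snps`` is an iterable of (snp_id, chrom, pos) triples
    (pos may be None for unplaced markers, which are skipped).  Distance
    is 0 for a SNP inside the gene, otherwise the gap to the nearest gene
    edge; results are sorted by distance.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in annotations:
        by_chrom.setdefault(g.chrom, []).append(g)
    out: dict[str, list[CandidateGene]] = {}
    for snp_id, chrom, pos in significant_snps:
        if pos is None:
            continue
        hits = []
        for g in by_chrom.get(chrom, []):
            if g.start <= pos <= g.end:
                d = 0
            else:
                d = min(abs(pos - g.start), abs(pos - g.end))
            if d <= window_bp:
                hits.append(CandidateGene(snp_id=snp_id, gene=g, distance=d))
        hits.sort(key=lambda h: (h.distance, h.gene.gene_id))
        out[snp_id] = hits
    return out
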