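"""Biophysical motif-affinity (TRAP-style) scoring of promoter windows.

For a PWM of width W with column probabilities p_j, the mismatch energy of a
site starting at offset i is

    E_i = (1/lambda) * sum_j ln(p_max,j / p_j(base at i+j))

and the occupancy of that site is R0 e^{-E_i} / (1 + R0 e^{-E_i}).  The
affinity of a sequence is the sum of occupancies over all offsets on both
strands -- the expected number of bound molecules -- and the score is its
natural logarithm.  Defaults lambda = 0.7 and ln R0 = 0.584 W - 5.66 are the
published TRAP parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .polii import TestResult, compare_groups

__all__ = [
    "PWMModel",
    "TrapScore",
    "WindowSpec",
    "trap_affinity",
    "score_regions",
    "sliding_scores",
    "motif_enrichment",
    "tertile_density",
    "pwm_from_consensus",
    "read_pwm",
    "IUPAC",
    "CORE_PROMOTER_CONSENSI",
]

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}

IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

# fly core-promoter consensus motifs used throughout the housekeeping /
# regulated promoter dichotomy
CORE_PROMOTER_CONSENSI: dict[str, str] = {
    "DRE": "WATCGATW",
    "motif1": "YGGTCCACTR",
    "Ebox": "CAGCTG",
    "DMv2": "TGGYAACR",
    "TATA": "TATAWAAR",
    "Inr": "TCAGTY",
    "DPE": "RGWYVT",
}


def default_ln_r0(width: int) -> float:
    return 0.584 * width - 5.66


@dataclass
class PWMModel:
    """Position-probability matrix (rows A,C,G,T) with TRAP energetics."""

    motif_id: str
    matrix: np.ndarray  # 4 x W, columns sum to 1
    lam: float = 0.7
    r0: float | None = None
    pseudocount: float = 0.01

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != 4 or m.shape[1] < 1:
            raise ValueError("PWM matrix must be 4 x W with W >= 1")
        if np.any(m < 0):
            raise ValueError("PWM probabilities must be nonnegative")
        sums = m.sum(axis=0)
        if np.any(sums <= 0):
            raise ValueError("PWM column sums must be positive")
        m = m / sums
        # regularize zeros: mix in a pseudocount fraction of the column
        f = self.pseudocount
        m = (m + f / 4.0) / (1.0 + f)
        self.matrix = m
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if self.r0 is None:
            self.r0 = float(np.exp(default_ln_r0(self.width)))
        if self.r0 <= 0:
            raise ValueError("R0 must be positive")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def energy_terms(self) -> np.ndarray:
        """(1/lambda) ln(p_max / p) per (base, position); shape 4 x W."""
        p = self.matrix
        return (np.log(p.max(axis=0, keepdims=True)) - np.log(p)) / self.lam


@dataclass(frozen=True)
class TrapScore:
    region_id: str
    motif_id: str
    affinity: float
    score: float  # ln(affinity)


@dataclass
class WindowSpec:
    """Strand-aware scoring windows relative to the TSS.

    ``default`` applies to every motif without a specific window.  The
    classical configuration scores most motifs in a 100 bp window around the
    TSS, with TATA at [-40,-20), Inr at [-20,+20) and DPE at [+20,+40); the
    enrichment-mode window is the full promoter [-200,+200).
    """

    default: tuple[int, int] = (-50, 50)
    per_motif: dict[str, tuple[int, int]] = field(default_factory=dict)

    @classmethod
    def tertile_mode(cls) -> "WindowSpec":
        return cls(
            default=(-50, 50),
            per_motif={"TATA": (-40, -20), "Inr": (-20, 20), "DPE": (20, 40)},
        )

    @classmethod
    def enrichment_mode(cls) -> "WindowSpec":
        return cls(default=(-200, 200))

    def window_for(self, motif_id: str) -> tuple[int, int]:
        return self.per_motif.get(motif_id, self.default)


def encode(seq: str) -> np.ndarray:
    return np.array([_CODE.get(b, -1) for b in seq.upper()], dtype=np.int64)


def revcomp(seq: str) -> str:
    return seq.upper().translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _site_occupancies(codes: np.ndarray, pwm: PWMModel) -> np.ndarray:
    """Occupancy per offset on one strand; sites containing N are skipped."""
    w = pwm.width
    n_sites = len(codes) - w + 1
    if n_sites <= 0:
        return np.zeros(0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    valid = (windows >= 0).all(axis=1)
    terms = pwm.energy_terms()  # 4 x W
    energy = np.zeros(n_sites)
    safe = np.where(windows < 0, 0, windows)
    energy = np.take_along_axis(terms.T, safe.T, axis=1).sum(axis=0)
    x = pwm.r0 * np.exp(-energy)
    occ = x / (1.0 + x)
    occ[~valid] = 0.0
    return occ


def trap_affinity(seq: str, pwm: PWMModel, strands: str = "both") -> TrapScore:
    """Expected bound-molecule count of ``seq`` for ``pwm``.

    Both strands are summed by default, so the affinity of a sequence equals
    that of its reverse complement exactly.
    """
    if len(seq) < pwm.width:
        raise ValueError(
            f"sequence shorter ({len(seq)}) than motif width ({pwm.width})"
        )
    occ = _site_occupancies(encode(seq), pwm)
    total = float(occ.sum())
    if strands == "both":
        occ_rc = _site_occupancies(encode(revcomp(seq)), pwm)
        total += float(occ_rc.sum())
    elif strands != "forward":
        raise ValueError(f"unknown strands option {strands!r}")
    score = float(np.log(total)) if total > 0 else float("-inf")
    return TrapScore(region_id="", motif_id=pwm.motif_id, affinity=total, score=score)


def score_regions(
    seqs: Mapping[str, str],
    pwms: Sequence[PWMModel],
    tss_offset: int,
    spec: WindowSpec | None = None,
) -> pd.DataFrame:
    """Score promoter sequences (already gene-oriented, 5'->3') per motif.

    ``tss_offset`` is the index of the TSS base within each sequence; window
    coordinates in ``spec`` are relative to it.  Windows falling outside a
    sequence, or windows with no valid (non-N) site, yield NaN.

    Returns a long DataFrame (region_id, motif_id, affinity, score).
    """
    spec = spec or WindowSpec()
    rows = []
    for pwm in pwms:
        lo, hi = spec.window_for(pwm.motif_id)
        for region_id, seq in seqs.items():
            a, b = tss_offset + lo, tss_offset + hi
            if a < 0 or b > len(seq) or b - a < pwm.width:
                rows.append((region_id, pwm.motif_id, np.nan, np.nan))
                continue
            ts = trap_affinity(seq[a:b], pwm)
            if ts.affinity <= 0:
                rows.append((region_id, pwm.motif_id, np.nan, np.nan))
            else:
                rows.append((region_id, pwm.motif_id, ts.affinity, ts.score))
    return pd.DataFrame(rows, columns=["region_id", "motif_id", "affinity", "score"])


def sliding_scores(
    seq: str,
    pwm: PWMModel,
    window: int = 40,
    step: int = 10,
) -> pd.DataFrame:
    """Per-window scores over a sequence (localization mode).

    Returns (window_start, window_end, affinity, score) with coordinates
    relative to the start of ``seq``.
    """
    rows = []
    for a in range(0, len(seq) - window + 1, step):
        sub = seq[a : a + window]
        if len(sub) < pwm.width:
            continue
        ts = trap_affinity(sub, pwm)
        rows.append(
            (a, a + window, ts.affinity, ts.score if ts.affinity > 0 else np.nan)
        )
    return pd.DataFrame(rows, columns=["window_start", "window_end", "affinity", "score"])


def significance_stars(p: float) -> str:
    """Star coding: **** <1e-4, *** <1e-3, ** <0.01, * <0.5, n.s. otherwise."""
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 0.5)):
        if p < cut:
            return stars
    return "n.s."


@dataclass
class MotifEnrichment:
    motif_id: str
    fold_change: float  # log(median bound / median non-bound)
    on_affinity_scale: bool
    test: TestResult
    stars: str


def motif_enrichment(
    scores_bound: pd.DataFrame | pd.Series,
    scores_nonbound: pd.DataFrame | pd.Series,
    motif_id: str = "",
) -> MotifEnrichment:
    """log median fold change of TRAP scores, bound vs non-bound promoters,
    plus a two-sided rank-sum test.

    If either median score is non-positive the fold change is computed on
    the affinity scale instead and flagged.
    """

    def _cols(x):
        if isinstance(x, pd.DataFrame):
            return x["score"].to_numpy(float), x["affinity"].to_numpy(float)
        arr = np.asarray(x, dtype=float)
        return arr, np.exp(arr)

    sb, ab = _cols(scores_bound)
    sn, an = _cols(scores_nonbound)
    sb, ab = sb[np.isfinite(sb)], ab[np.isfinite(ab)]
    sn, an = sn[np.isfinite(sn)], an[np.isfinite(an)]
    if len(sb) == 0 or len(sn) == 0:
        raise ValueError("both groups must be nonempty")
    med_b, med_n = np.median(sb), np.median(sn)
    if med_b > 0 and med_n > 0:
        fold = float(np.log(med_b / med_n))
        on_affinity = False
    else:
        fold = float(np.log(np.median(ab) / np.median(an)))
        on_affinity = True
    test = compare_groups(sb, sn)
    return MotifEnrichment(
        motif_id=motif_id,
        fold_change=fold,
        on_affinity_scale=on_affinity,
        test=test,
        stars=significance_stars(test.pvalue),
    )


@dataclass
class TertileAssociation:
    """Median-score difference between the most- and least-affected strata."""

    motif_id: str
    group: str  # "bound" or "nonbound"
    medians: dict[int, float]
    n: dict[int, int]
    summary: float  # median(stratum 1) - median(stratum 3)
    test: TestResult


def tertile_density(
    scores: pd.Series,
    strata: pd.Series,
    bound: pd.Series,
    motif_id: str = "",
) -> dict[str, TertileAssociation]:
    """Associate motif strength with knockdown-response tertiles.

    ``scores``, ``strata`` (1 = most severe Pol II loss) and ``bound`` are
    indexed by gene id; genes missing from any input are dropped.  Returns
    per-group (bound / nonbound) stratum score vectors summarized as the
    median difference stratum 1 - stratum 3 with a rank-sum p-value.
    """
    df = pd.DataFrame({"score": scores, "stratum": strata, "bound": bound}).dropna()
    out = {}
    for group, flag in (("bound", True), ("nonbound", False)):
        sub = df[df["bound"] == flag]
        vecs = {
            s: sub.loc[sub["stratum"] == s, "score"].to_numpy(float)
            for s in (1, 2, 3)
        }
        if any(len(v) == 0 for v in vecs.values()):
            raise ValueError(f"empty stratum in group {group!r}")
        test = compare_groups(vecs[1], vecs[3])
        out[group] = TertileAssociation(
            motif_id=motif_id,
            group=group,
            medians={s: float(np.median(v)) for s, v in vecs.items()},
            n={s: len(v) for s, v in vecs.items()},
            summary=float(np.median(vecs[1]) - np.median(vecs[3])),
            test=test,
        )
    return out


# ---------------------------------------------------------------------------
# PWM construction and parsing
# ---------------------------------------------------------------------------


def pwm_from_consensus(
    motif_id: str,
    consensus: str | None = None,
    match_prob: float = 0.94,
    **kwargs,
) -> PWMModel:
    """Soft PWM from an IUPAC consensus: allowed bases share ``match_prob``
    of each column, the rest is spread over disallowed bases."""
    consensus = consensus or CORE_PROMOTER_CONSENSI[motif_id]
    w = len(consensus)
    m = np.zeros((4, w))
    for j, sym in enumerate(consensus.upper()):
        allowed = IUPAC.get(sym)
        if allowed is None:
            raise ValueError(f"bad IUPAC symbol {sym!r} in consensus")
        n_allowed = len(allowed)
        if n_allowed == 4:
            m[:, j] = 0.25
            continue
        for b in _BASES:
            if b in allowed:
                m[_CODE[b], j] = match_prob / n_allowed
            else:
                m[_CODE[b], j] = (1 - match_prob) / (4 - n_allowed)
    return PWMModel(motif_id=motif_id, matrix=m, **kwargs)


def read_pwm(path, motif_id: str | None = None, **kwargs) -> PWMModel:
    """Read a PWM from a tab-delimited 4-row matrix or a JASPAR-style count
    matrix ('A [ 1 2 3 ]'); counts are normalized on read."""
    rows: dict[str, list[float]] = {}
    order = []
    header_id = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                header_id = line[1:].split()[0]
                continue
            if "[" in line:  # JASPAR
                base, rest = line.split("[", 1)
                base = base.strip()[:1].upper()
                vals = [float(tok) for tok in rest.replace("]", "").split()]
            else:
                toks = line.replace(",", "\t").split()
                if toks[0][:1].upper() in _BASES and not _is_number(toks[0]):
                    base, vals = toks[0][:1].upper(), [float(t) for t in toks[1:]]
                else:
                    base = _BASES[len(order)]
                    vals = [float(t) for t in toks]
            rows[base] = vals
            order.append(base)
    if set(rows) != set(_BASES):
        raise ValueError(f"PWM file {path} must provide rows for A, C, G, T")
    m = np.array([rows[b] for b in _BASES], dtype=float)
    return PWMModel(motif_id=motif_id or header_id or Path(path).stem, matrix=m, **kwargs)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False
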