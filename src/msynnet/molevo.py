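"""Codon-level molecular evolution: protein alignment, back-translation and
Nei–Gojobori (1986) Ka/Ks estimation.

The estimator follows the classical counting recipe: per-codon synonymous
site fractions (number of synonymous one-step changes divided by three,
averaged between the two sequences), difference counting over all minimal
substitution pathways with equal pathway weights (pathways passing through a
stop codon are excluded), and a Jukes–Cantor multiple-hit correction of the
raw proportions.  Proportions beyond the correctable range are reported as
saturated rather than extrapolated.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

NUCLEOTIDES = "ACGT"
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS = tuple(sorted(standard_dna_table.forward_table))
#: codon -> encoded amino acid (sense codons only)
CODON_TO_AA = dict(standard_dna_table.forward_table)

_VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")


def _synonymous_site_fraction(codon: str) -> float:
    """NG86 synonymous site count of one codon.

    Each position contributes (number of synonymous one-step changes)/3;
    changes that create a stop codon count as nonsynonymous.
    """
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt not in STOP_CODONS and CODON_TO_AA[alt] == aa:
                s += 1.0
    return s / 3.0


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) difference counts between two
    sense codons over all minimal substitution pathways.

    Pathways with a stop-codon intermediate are excluded; if every pathway
    is excluded the average falls back to all pathways (cannot happen for
    1-step differences, and is vanishingly rare otherwise).
    """
    diff_positions = [p for p in range(3) if c1[p] != c2[p]]
    valid: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in itertools.permutations(diff_positions):
        current = c1
        sd = nd = 0
        through_stop = False
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                through_stop = True
                break
            if CODON_TO_AA[current] == CODON_TO_AA[nxt]:
                sd += 1
            else:
                nd += 1
            current = nxt
        if through_stop:
            blocked.append((0, 0))
        else:
            valid.append((sd, nd))
    if not valid:
        # recompute ignoring the stop exclusion
        for order in itertools.permutations(diff_positions):
            current = c1
            sd = nd = 0
            for pos in order:
                nxt = current[:pos] + c2[pos] + current[pos + 1 :]
                if CODON_TO_AA.get(current, "*") == CODON_TO_AA.get(nxt, "*"):
                    sd += 1
                else:
                    nd += 1
                current = nxt
            valid.append((sd, nd))
    sd_mean = sum(v[0] for v in valid) / len(valid)
    nd_mean = sum(v[1] for v in valid) / len(valid)
    return sd_mean, nd_mean


# Precomputed lookup tables (61 sense codons; ~1.9k ordered pairs with diffs).
SYN_SITES: dict[str, float] = {c: _synonymous_site_fraction(c) for c in SENSE_CODONS}
_PAIR_COUNTS: dict[tuple[str, str], tuple[float, float]] = {}
for _c1 in SENSE_CODONS:
    for _c2 in SENSE_CODONS:
        if _c1 != _c2:
            _PAIR_COUNTS[(_c1, _c2)] = _pathway_counts(_c1, _c2)


@dataclass(frozen=True)
class CodonAlignment:
    """Two aligned coding sequences; every 3-column unit is a codon or '---'."""

    id_a: str
    id_b: str
    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned rows differ in length")
        if len(self.seq_a) % 3 != 0:
            raise ValueError("alignment length not divisible by 3")

    def codon_columns(self) -> Iterable[tuple[str, str]]:
        for k in range(0, len(self.seq_a), 3):
            yield self.seq_a[k : k + 3], self.seq_b[k : k + 3]


@dataclass(frozen=True)
class KsEstimate:
    """NG86 site/difference counts and Jukes–Cantor distances for one pair."""

    S: float
    N: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    Ks: float | None
    Ka: float | None
    omega: float | None
    saturated: bool
    n_codons: int


class SaturationError(ValueError):
    pass


def _jc_correct(p: float) -> float | None:
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        return None
    return -0.75 * math.log(arg)


def ng86(aln: CodonAlignment) -> KsEstimate:
    """Nei–Gojobori (1986) Ka/Ks for one codon alignment.

    Gapped or ambiguous codon columns are excluded from the counts.  The
    estimate is symmetric in the two rows.  Raises ``ValueError`` when no
    comparable codon remains.
    """
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for ca, cb in aln.codon_columns():
        if ca not in CODON_TO_AA or cb not in CODON_TO_AA:
            if "-" not in ca + cb:
                logger.debug("excluding non-standard codon column %s/%s", ca, cb)
            continue
        n_codons += 1
        S += 0.5 * (SYN_SITES[ca] + SYN_SITES[cb])
        if ca != cb:
            sd, nd = _PAIR_COUNTS[(ca, cb)]
            Sd += sd
            Nd += nd
    if n_codons == 0:
        raise ValueError(
            f"no comparable codons between {aln.id_a} and {aln.id_b}"
        )
    N = 3.0 * n_codons - S
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    Ks = _jc_correct(ps)
    Ka = _jc_correct(pn)
    saturated = Ks is None or Ka is None
    omega = None
    if Ka is not None and Ks is not None and Ks > 0:
        omega = Ka / Ks
    return KsEstimate(
        S=S, N=N, Sd=Sd, Nd=Nd, ps=ps, pn=pn,
        Ks=Ks, Ka=Ka, omega=omega, saturated=saturated, n_codons=n_codons,
    )


_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def align_proteins(p1: str, p2: str) -> tuple[str, str, float]:
    """Global Needleman–Wunsch alignment (BLOSUM62, gap open 10 / extend 0.5).

    Returns the two aligned rows (with ``-`` gaps) and the score.  The first
    optimal traceback reported by the aligner is used, which is deterministic
    for fixed inputs.
    """
    for name, p in (("first", p1), ("second", p2)):
        if not p:
            raise ValueError(f"{name} protein sequence is empty")
        bad = set(p) - _VALID_AA
        if bad:
            raise ValueError(f"non-amino-acid symbol(s) {sorted(bad)} in {name} sequence")
    aligner = _make_aligner()
    alignment = next(iter(aligner.align(p1, p2)))
    a, b = str(alignment[0]), str(alignment[1])
    return a, b, alignment.score


def _strip_terminal_stop(cds: str) -> str:
    if len(cds) >= 3 and cds[-3:].upper() in STOP_CODONS:
        return cds[:-3]
    return cds


def translate_cds(cds: str) -> str:
    """Translate a CDS (standard code), stripping one terminal stop codon."""
    cds = _strip_terminal_stop(cds.upper())
    if len(cds) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    protein = str(Seq(cds).translate())
    if "*" in protein:
        raise ValueError("internal stop codon in CDS")
    return protein


def backtranslate(
    aligned_p1: str,
    aligned_p2: str,
    cds1: str,
    cds2: str,
    id1: str = "seq1",
    id2: str = "seq2",
) -> CodonAlignment:
    """Thread CDSs through a protein alignment to build a codon alignment."""
    rows = []
    for aligned, cds, gid in ((aligned_p1, cds1, id1), (aligned_p2, cds2, id2)):
        cds = _strip_terminal_stop(cds.upper())
        protein = aligned.replace("-", "")
        if len(cds) != 3 * len(protein):
            raise ValueError(
                f"{gid}: CDS length {len(cds)} does not match protein length {len(protein)}"
            )
        if translate_cds(cds) != protein:
            raise ValueError(f"{gid}: CDS does not translate to the aligned protein")
        out = []
        k = 0
        for residue in aligned:
            if residue == "-":
                out.append("---")
            else:
                out.append(cds[3 * k : 3 * k + 3])
                k += 1
        rows.append("".join(out))
    return CodonAlignment(id_a=id1, id_b=id2, seq_a=rows[0], seq_b=rows[1])


def pairwise_ks(cds1: str, cds2: str, id1: str = "seq1", id2: str = "seq2") -> KsEstimate:
    """Align two CDSs at the protein level, back-translate and run NG86."""
    p1, p2 = translate_cds(cds1), translate_cds(cds2)
    a1, a2, _ = align_proteins(p1, p2)
    return ng86(backtranslate(a1, a2, cds1, cds2, id1, id2))


def count_pairs(n: int) -> int:
    """Number of unordered pairwise comparisons among n sequences."""
    if n < 0:
        raise ValueError("n must be non-negative")
    return n * (n - 1) // 2


def group_ks(
    groups: Mapping[str, Sequence[str]],
    cds: Mapping[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Ks within each group of gene ids.

    Returns ``(summary, pairs)`` data frames.  Saturated pairs are excluded
    from the mean and quartiles but reported in ``n_saturated``; quartiles
    use linear interpolation between order statistics.
    """
    pair_rows = []
    summary_rows = []
    for group, members in groups.items():
        members = sorted(members)
        if len(members) < 2:
            logger.warning("group %s has fewer than 2 members; skipped", group)
            continue
        ks_values = []
        n_sat = 0
        for ga, gb in itertools.combinations(members, 2):
            est = pairwise_ks(cds[ga], cds[gb], ga, gb)
            pair_rows.append(
                {
                    "group": group, "gene_a": ga, "gene_b": gb,
                    "S": est.S, "N": est.N, "Sd": est.Sd, "Nd": est.Nd,
                    "ps": est.ps, "pn": est.pn,
                    "Ka": est.Ka if est.Ka is not None else float("nan"),
                    "Ks": est.Ks if est.Ks is not None else float("nan"),
                    "omega": est.omega if est.omega is not None else float("nan"),
                    "saturated": est.saturated,
                }
            )
            if est.Ks is None:
                n_sat += 1
            else:
                ks_values.append(est.Ks)
        n_pairs = count_pairs(len(members))
        if ks_values:
            q1, med, q3 = np.percentile(ks_values, [25, 50, 75])
            mean = float(np.mean(ks_values))
        else:
            q1 = med = q3 = mean = float("nan")
        summary_rows.append(
            {
                "group": group, "n_genes": len(members), "n_pairs": n_pairs,
                "n_saturated": n_sat, "mean_Ks": mean,
                "Fst_Qu": float(q1), "median_Ks": float(med), "Trd_Qu": float(q3),
            }
        )
    return pd.DataFrame(summary_rows), pd.DataFrame(pair_rows)
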