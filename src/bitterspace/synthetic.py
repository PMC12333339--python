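"""Seeded generator of collection-like peptide datasets.

The generator emulates the statistical structure of a curated bitter /
nonbitter peptide collection so that every analysis stage is testable
without the curated data itself:

* 570 bitter and 423 nonbitter records in total, of which 213 are
  modified peptides in six modification groups (cyclic 59, salts/esters
  26, pyroglutamyl 14, gamma-Glu/Asp 57, Nle/Nva 14, other 43);
* a length law peaking at dipeptides, with class maxima of 49 (bitter)
  and 56 (nonbitter) residues;
* class-conditional residue frequencies — bitter sequences over-sample
  F, G, I, L, P, R, V, W, Y and nonbitter over-sample A, D, E, M, S, T —
  sharpened by a Q-logistic label law (acceptance probability logistic
  in the Ney Q value, midpoint near 1350 cal/mol), so the
  hydrophobicity-vs-taste enrichment the analysis looks for is present
  by construction but blurs at low Q, as in real sensory data;
* bitter taste thresholds spanning 0.002-519 mmol/L with ~86% of values
  below 10 mmol/L, and sparse TAS2R annotations.

One integer seed drives a single numpy Generator stream; identical
seeds give identical record lists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import notation, scoring
from .dataset import SOURCE_VALUES, TAS2R_VOCABULARY, PeptideRecord
from .monomers import MonomerLibrary, core_library

__all__ = ["GeneratorConfig", "generate", "generate_worked_examples"]

_BITTER_HOT = "FGILPRVWY"
_NONBITTER_HOT = "ADEMST"
_ALL = "ACDEFGHIKLMNPQRSTVWY"


def _class_frequencies(hot: str, hot_weight: float, boost: dict[str, float] | None = None):
    boost = boost or {}
    w = {}
    cold = [r for r in _ALL if r not in hot]
    for r in _ALL:
        w[r] = hot_weight / len(hot) if r in hot else (1.0 - hot_weight) / len(cold)
    for r, v in boost.items():
        w[r] = v
    total = sum(w.values())
    return {r: v / total for r, v in w.items()}


# P is the most common residue in both classes of the real collection.
BITTER_FREQUENCIES = _class_frequencies(_BITTER_HOT, 0.62, {"P": 0.12})
NONBITTER_FREQUENCIES = _class_frequencies(_NONBITTER_HOT, 0.48, {"P": 0.08, "G": 0.05})

DEFAULT_GROUP_COUNTS = {2: 59, 3: 26, 4: 14, 5: 57, 6: 14, 7: 43}
# Chosen to match the reported group-wise bitter fractions (cyclic 74.6%,
# Nle/Nva 100%, gamma-Glu/Asp 12.3% bitter; 92 bitter modified overall).
DEFAULT_GROUP_BITTER_COUNTS = {2: 44, 3: 8, 4: 4, 5: 7, 6: 14, 7: 15}


class GeneratorError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one generated dataset (defaults emulate the
    curated collection's composition)."""

    seed: int = 0
    n_bitter: int = 570
    n_nonbitter: int = 423
    n_modified: int = 213
    group_counts: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_COUNTS)
    )
    group_bitter_counts: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_BITTER_COUNTS)
    )
    #: length law: P(1) = p_length1, then geometric decay from the mode (2).
    p_length1: float = 0.08
    length_ratio: float = 0.80
    max_bitter_length: int = 49
    max_nonbitter_length: int = 56
    #: BTT law: mixture of log-uniform bands, btt_frac_low below btt_low_edge.
    btt_min: float = 0.002
    btt_max: float = 519.0
    btt_low_edge: float = 10.0
    btt_frac_low: float = 0.86
    btt_fraction: float = 0.60  # fraction of bitter records carrying a BTT
    #: Q-logistic label law: acceptance ~ 1/(1+exp(-slope*(Q-midpoint))).
    q_midpoint: float = 1350.0
    q_slope: float = 0.0025
    receptor_fraction: float = 0.05
    conflict_fraction: float = 0.03

    def validate(self) -> None:
        if min(self.n_bitter, self.n_nonbitter, self.n_modified) < 0:
            raise GeneratorError("counts must be nonnegative")
        if set(self.group_counts) - {2, 3, 4, 5, 6, 7}:
            raise GeneratorError("modification groups must be in 2..7")
        if sum(self.group_counts.values()) != self.n_modified:
            raise GeneratorError(
                f"group counts sum to {sum(self.group_counts.values())}, "
                f"expected n_modified={self.n_modified}"
            )
        n_mod_bitter = sum(self.group_bitter_counts.values())
        for g, nb in self.group_bitter_counts.items():
            if nb > self.group_counts.get(g, 0):
                raise GeneratorError(f"group {g}: bitter count {nb} exceeds group size")
        if n_mod_bitter > self.n_bitter:
            raise GeneratorError("modified bitter count exceeds n_bitter")
        if self.n_modified - n_mod_bitter > self.n_nonbitter:
            raise GeneratorError("modified nonbitter count exceeds n_nonbitter")
        if not (0 <= self.btt_frac_low <= 1 and 0 <= self.btt_fraction <= 1):
            raise GeneratorError("btt probabilities must lie in [0, 1]")
        if not 0 < self.btt_min < self.btt_max:
            raise GeneratorError("btt range must satisfy 0 < min < max")


def _sample_length(rng: np.random.Generator, cfg: GeneratorConfig, max_len: int) -> int:
    weights = np.empty(max_len)
    weights[0] = cfg.p_length1
    weights[1:] = (1.0 - cfg.p_length1) * (
        cfg.length_ratio ** np.arange(max_len - 1)
    ) * (1.0 - cfg.length_ratio)
    weights /= weights.sum()
    return int(rng.choice(np.arange(1, max_len + 1), p=weights))


def _acceptance(q: float, cfg: GeneratorConfig, bitter: bool) -> float:
    p = 1.0 / (1.0 + math.exp(-cfg.q_slope * (q - cfg.q_midpoint)))
    return p if bitter else 1.0 - p


def _sample_canonical(
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    bitter: bool,
    seen: set[str],
    min_len: int = 1,
    max_len: int | None = None,
) -> str:
    freqs = BITTER_FREQUENCIES if bitter else NONBITTER_FREQUENCIES
    residues = np.array(list(freqs))
    probs = np.array(list(freqs.values()))
    cap = max_len or (cfg.max_bitter_length if bitter else cfg.max_nonbitter_length)
    best, best_p = None, -1.0
    for _ in range(200):
        n = max(min_len, _sample_length(rng, cfg, cap))
        seq = "".join(rng.choice(residues, size=n, p=probs))
        p = _acceptance(scoring.q_value(seq).value, cfg, bitter)
        if p > best_p and seq not in seen:
            best, best_p = seq, p
        if rng.random() < p and seq not in seen:
            seen.add(seq)
            return seq
    if best is None:  # pathological config; give up on uniqueness
        return "".join(rng.choice(residues, size=max(min_len, 2), p=probs))
    seen.add(best)
    return best


def _sample_btt(rng: np.random.Generator, cfg: GeneratorConfig) -> float:
    if rng.random() < cfg.btt_frac_low:
        lo, hi = cfg.btt_min, cfg.btt_low_edge
    else:
        lo, hi = cfg.btt_low_edge, cfg.btt_max
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


_SOURCE_WEIGHTS = (0.45, 0.38, 0.05, 0.05, 0.07)  # animal, plant, yeast, mixed, other


def _common_fields(rng: np.random.Generator, cfg: GeneratorConfig, bitter: bool) -> dict:
    fields: dict = {
        "taste": "bitter" if bitter else "nonbitter",
        "conflict": bool(rng.random() < cfg.conflict_fraction),
        "source": str(rng.choice(SOURCE_VALUES, p=_SOURCE_WEIGHTS)),
    }
    if bitter and rng.random() < cfg.btt_fraction:
        fields["btt"] = _sample_btt(rng, cfg)
    if bitter and rng.random() < cfg.receptor_fraction:
        k = int(rng.integers(1, 4))
        fields["receptors"] = tuple(
            sorted(rng.choice(sorted(TAS2R_VOCABULARY), size=k, replace=False))
        )
    return fields


def _modified_fasta(
    rng: np.random.Generator, cfg: GeneratorConfig, group: int, bitter: bool, seen: set[str]
) -> str:
    """Build the extended-FASTA of one modified record: a canonical
    backbone plus the group's defining transformation."""
    if group == 2:  # head-to-tail cyclic (cyclolinopeptide-like sizes)
        backbone = _sample_canonical(rng, cfg, bitter, seen, min_len=5, max_len=9)
        return f"cyclo({backbone})"
    if group == 3:  # terminal ester/acyl caps standing in for salts & esters
        backbone = _sample_canonical(rng, cfg, bitter, seen, min_len=2, max_len=4)
        cap = str(rng.choice(["OMe", "Lac", "Succ", "Ac"]))
        return f"{backbone}[OMe]" if cap == "OMe" else f"[{cap}]{backbone}"
    if group == 4:  # pyroglutamyl N-terminus
        backbone = _sample_canonical(rng, cfg, bitter, seen, min_len=1, max_len=3)
        return f"[pGlu]{backbone}"
    if group == 5:  # gamma-glutamyl / gamma-aspartyl linkage
        backbone = _sample_canonical(rng, cfg, bitter, seen, min_len=1, max_len=2)
        prefix = "gE-" if rng.random() < 0.8 else "gD-"
        return prefix + backbone
    if group == 6:  # norleucine / norvaline substitution
        backbone = _sample_canonical(rng, cfg, bitter, seen, min_len=2, max_len=4)
        pos = int(rng.integers(0, len(backbone)))
        sub = "[Nle]" if rng.random() < 0.5 else "[Nva]"
        return backbone[:pos] + sub + backbone[pos + 1 :]
    if group == 7:  # ornithine, Met-sulfoxide, phospho, D-residues, ...
        backbone = _sample_canonical(rng, cfg, bitter, seen, min_len=2, max_len=4)
        pos = int(rng.integers(0, len(backbone)))
        sub = str(rng.choice(["[Orn]", "[M(O)]", "[pS]", "(D)-L", "(D)-F", "(D)-W"]))
        return backbone[:pos] + sub + backbone[pos + 1 :]
    raise GeneratorError(f"unknown modification group {group}")


def _notations(fasta: str, lib: MonomerLibrary) -> tuple[str, str]:
    seq = notation.parse_fasta_extended(fasta, lib)
    return notation.write_helm(seq), notation.write_biln(seq)


def generate(config: GeneratorConfig | None = None) -> list[PeptideRecord]:
    """Generate a validated, seed-deterministic record list with exactly
    the configured class and modification-group counts."""
    cfg = config or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    lib = core_library()
    seen: set[str] = set()
    records: list[PeptideRecord] = []

    n_mod_bitter = sum(cfg.group_bitter_counts.values())
    n_mod_nonbitter = cfg.n_modified - n_mod_bitter
    n_canon_bitter = cfg.n_bitter - n_mod_bitter
    n_canon_nonbitter = cfg.n_nonbitter - n_mod_nonbitter

    counter = 0
    for bitter, n in ((True, n_canon_bitter), (False, n_canon_nonbitter)):
        for _ in range(n):
            counter += 1
            seq = _sample_canonical(rng, cfg, bitter, seen)
            records.append(
                PeptideRecord(
                    id=f"SYN{counter:04d}",
                    fasta=seq,
                    helm=notation.write_helm(
                        notation.PeptideSequence(chains=[list(seq)])
                    ),
                    biln="-".join(seq),
                    canonical=True,
                    mod_group=1,
                    **_common_fields(rng, cfg, bitter),
                )
            )
    for group in sorted(cfg.group_counts):
        n_total = cfg.group_counts[group]
        n_bitter = cfg.group_bitter_counts.get(group, 0)
        for j in range(n_total):
            counter += 1
            bitter = j < n_bitter
            fasta = _modified_fasta(rng, cfg, group, bitter, seen)
            helm, biln = _notations(fasta, lib)
            records.append(
                PeptideRecord(
                    id=f"SYN{counter:04d}",
                    fasta=fasta,
                    helm=helm,
                    biln=biln,
                    canonical=False,
                    mod_group=group,
                    **_common_fields(rng, cfg, bitter),
                )
            )

    problems = [p for r in records for p in r.validate()]
    if problems:  # generator bug, not a user error
        raise GeneratorError("generated invalid records: " + "; ".join(problems[:5]))
    return records


_WORKED_56MER = (
    "YPVQPFTESQSLTLTDVENLHLPPLLLQSWMHQPHQPLPPTVMFPPQSVLSLSQSK"
)


def generate_worked_examples() -> list[PeptideRecord]:
    """Deterministic fixture of the collection's printed worked examples:
    the extreme-Q peptides (WW, Q), the BTT extremes (RRPPPFFF at 0.002
    mmol/L; GE and GF at 403 and 519 mmol/L), receptor-profiled peptides
    (WWW, FFPR), the smallest amino acid G, and the longest (56-residue)
    nonbitter peptide."""
    lib = core_library()

    def rec(id_, fasta, **kw) -> PeptideRecord:
        helm, biln = _notations(fasta, lib)
        return PeptideRecord(id=id_, fasta=fasta, helm=helm, biln=biln, **kw)

    return [
        rec("WW", "WW", taste="bitter"),
        rec("Q", "Q", taste="nonbitter"),
        rec("GE", "GE", taste="bitter", btt=403.0),
        rec("GF", "GF", taste="bitter", btt=519.0,
            receptors=("TAS2R1", "TAS2R4", "TAS2R14", "TAS2R16")),
        rec("RRPPPFFF", "RRPPPFFF", taste="bitter", btt=0.002),
        rec("G", "G", taste="nonbitter"),
        rec("WWW", "WWW", taste="bitter",
            receptors=("TAS2R1", "TAS2R4", "TAS2R14", "TAS2R39", "TAS2R46")),
        rec("FFPR", "FFPR", taste="bitter", receptors=("TAS2R8", "TAS2R39")),
        rec("LONG56", _WORKED_56MER, taste="nonbitter"),
    ]
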