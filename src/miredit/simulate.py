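"""Synthetic cohort generator.

The study design being emulated: small-RNA sequencing of 60 tumour and 48
control tissue samples (50-bp single-end reads carrying a 3' adapter), a
mature-miRNA reference, a gene-level count matrix from a two-arm mimic
experiment, 3'UTR sequences, a predicted-target list, a clinical table
and qPCR runs.  One seed-region site of one miRNA is over-edited in the
tumour group, and the simulated hazard increases with the editing level
so that editing correlates negatively with overall survival.

Every generator is a pure function of (parameters, seed): rerunning with
the same truth and seed reproduces byte-identical files.  Ground truth is
recorded in a :class:`SimTruth` sidecar so recovery can be checked
exactly.

Sequencing errors are uniform across the read and substitution-symmetric
(rate e per base, e/3 per specific change), matching the detector's
null.  Phred symbols encode the quality corresponding to e.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .align import MatureMiRNA
from .expression import CountMatrix

__all__ = [
    "SimTruth",
    "SyntheticBundle",
    "DEFAULT_REFERENCE",
    "SYNTHETIC_MXI1_UTR",
    "simulate_reads",
    "simulate_counts",
    "simulate_clinical",
    "simulate_utrs",
    "simulate_qpcr",
    "simulate_bundle",
]

# Illumina TruSeq small-RNA 3' adapter
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

WT_MIR200B = "UAAUACUGCCUGGUAAUGAUGA"  # mature hsa-miR-200b-3p (miRBase)

# A small mature-miRNA reference panel (miRBase mature sequences).  The
# panel includes miR-200b-3p (the edited miRNA), the two reference miRNAs
# used for qPCR normalisation, and assorted abundant miRNAs.
DEFAULT_REFERENCE: tuple[tuple[str, str], ...] = (
    ("hsa-miR-200b-3p", WT_MIR200B),
    ("hsa-miR-103a-3p", "AGCAGCAUUGUACAGGGCUAUGA"),
    ("hsa-miR-199b-5p", "CCCAGUGUUUAGACUAUCUGUUC"),
    ("hsa-miR-21-5p", "UAGCUUAUCAGACUGAUGUUGA"),
    ("hsa-miR-22-3p", "AAGCUGCCAGUUGAAGAACUGU"),
    ("hsa-miR-26a-5p", "UUCAAGUAAUCCAGGAUAGGCU"),
    ("hsa-miR-30d-5p", "UGUAAACAUCCCCGACUGGAAG"),
    ("hsa-miR-92a-3p", "UAUUGCACUUGUCCCGGCCUGU"),
    ("hsa-miR-99b-5p", "CACCCGUAGAACCGACCUUGCG"),
    ("hsa-miR-100-5p", "AACCCGUAGAUCCGAACUUGUG"),
    ("hsa-miR-125b-5p", "UCCCUGAGACCCUAACUUGUGA"),
    ("hsa-miR-141-3p", "UAACACUGUCUGGUAAAGAUGG"),
    ("hsa-miR-143-3p", "UGAGAUGAAGCACUGUAGCUC"),
    ("hsa-miR-148a-3p", "UCAGUGCACUACAGAACUUUGU"),
    ("hsa-miR-182-5p", "UUUGGCAAUGGUAGAACUCACACU"),
    ("hsa-miR-183-5p", "UAUGGCACUGGUAGAAUUCACU"),
    ("hsa-miR-191-5p", "CAACGGAAUCCCAAAAGCAGCUG"),
    ("hsa-miR-200a-3p", "UAACACUGUCUGGUAACGAUGU"),
    ("hsa-miR-200c-3p", "UAAUACUGCCGGGUAAUGAUGGA"),
    ("hsa-miR-203a-3p", "GUGAAAUGUUUAGGACCACUAG"),
    ("hsa-miR-205-5p", "UCCUUCAUUCCACCGGAGUCUG"),
    ("hsa-miR-375-3p", "UUUGUUCGUUCGGCUCGCGUGA"),
    ("hsa-miR-429", "UAAUACUGUCUGGUAAAACCGU"),
    ("hsa-let-7a-5p", "UGAGGUAGUAGGUUGUAUAGUU"),
    ("hsa-let-7b-5p", "UGAGGUAGUAGGUUGUGUGGUU"),
)

# Synthetic stand-in for the MXI1 3'UTR: a generated sequence constructed
# to carry three edited-miR-200b-3p binding sites (8mer, core CAGCATT
# followed by A) and no wild-type miR-200b-3p site (core CAGTATT absent).
# It is NOT the genomic MXI1 3'UTR.
SYNTHETIC_MXI1_UTR = (
    "ATCATGTAAAGATAACTGTCACGTTTTACGGATGAGGAAATTGTTTCAACACAATGGAAT"
    "AACCCCAGCCCAGGGCAAGGCAGCACTCCGCAGCATTATAAGCGACGGAGCAGTCCACCC"
    "ATTTATTGGCACGCGGTCTCCCTTCCGATGACACCAACGGCTCCGCCCATCGGGTTTATT"
    "GGGTTTTGTGGAAGCTGTCGATCACCAGCAGCATTACCTAGGCAAGGGTAAGGGTGCTAA"
    "ATGCAGGACTGCGAGGAACAAACGTTCTCTGCGACTAGGAGGTTGACCGTGGCGAGATCC"
    "CGTGAAGATAACAGCATTAACCTAGAAGATTGGATCATCAGAGTGAACATGACCAGGCCC"
    "TATCGAGTTGTTATGGGTTCTAGATTTACAGCGCTGGAT"
)

_BASES = np.array(list("ACGT"))
_RNA_TO_DNA = str.maketrans("uU", "tT")


def _dna(seq: str) -> str:
    return seq.translate(_RNA_TO_DNA).upper()


def _default_isomir_offsets() -> dict[int, float]:
    return {0: 0.80, 1: 0.08, -1: 0.08, 2: 0.02, -2: 0.02}


def _default_trim3() -> dict[int, float]:
    return {0: 0.80, 1: 0.15, 2: 0.05}


@dataclass
class SimTruth:
    """Ground truth behind a synthetic bundle.

    ``edit_fractions`` holds the control-group editing fraction per
    (miRNA id, 1-based mature position); sites listed in
    ``differential_sites`` get ``group_effect`` added in the tumour
    group.  ``survival_beta`` couples the (standardised) editing level to
    log mean survival time: negative values shorten survival for highly
    edited samples.
    """

    mirna_abundances: dict[str, float]
    edit_fractions: dict[tuple[str, int], float]
    per_base_error: float = 0.001
    adapter: str = DEFAULT_ADAPTER
    isomir_offsets: dict[int, float] = field(default_factory=_default_isomir_offsets)
    trim3_probs: dict[int, float] = field(default_factory=_default_trim3)
    group_effect: float = 0.09
    survival_beta: float = -0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for (m, p), f in self.edit_fractions.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"editing fraction for {m}:{p} outside [0,1]: {f}")
        if any(a < 0 for a in self.mirna_abundances.values()):
            raise ValueError("abundances must be >= 0")
        if not (0.0 <= self.per_base_error <= 0.05):
            raise ValueError("per-base error must lie in [0, 0.05]")

    differential_sites: tuple[tuple[str, int], ...] = (("hsa-miR-200b-3p", 5),)

    def tumour_fraction(self, site: tuple[str, int]) -> float:
        f = self.edit_fractions.get(site, 0.0)
        if site in self.differential_sites:
            f = min(1.0, f + self.group_effect)
        return f

    def to_json(self, path: str | os.PathLike) -> None:
        d = dataclasses.asdict(self)
        d["edit_fractions"] = {f"{m}:{p}": v for (m, p), v in d["edit_fractions"].items()}
        d["differential_sites"] = [f"{m}:{p}" for m, p in self.differential_sites]
        d["isomir_offsets"] = {str(k): v for k, v in d["isomir_offsets"].items()}
        d["trim3_probs"] = {str(k): v for k, v in d["trim3_probs"].items()}
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "SimTruth":
        d = json.loads(Path(path).read_text())
        d["edit_fractions"] = {
            (k.rsplit(":", 1)[0], int(k.rsplit(":", 1)[1])): v
            for k, v in d["edit_fractions"].items()
        }
        d["differential_sites"] = tuple(
            (k.rsplit(":", 1)[0], int(k.rsplit(":", 1)[1]))
            for k in d["differential_sites"]
        )
        d["isomir_offsets"] = {int(k): v for k, v in d["isomir_offsets"].items()}
        d["trim3_probs"] = {int(k): v for k, v in d["trim3_probs"].items()}
        return cls(**d)


def default_truth(seed: int = 0, per_base_error: float = 0.001) -> SimTruth:
    """Study-condition defaults: miR-200b-3p position 5 edited at 1% in
    control tissue and 10% in tumours, miR-200b among the more abundant
    panel members."""
    rng = np.random.default_rng([seed, 101])
    abundances = {}
    for mid, _ in DEFAULT_REFERENCE:
        abundances[mid] = float(rng.lognormal(mean=0.0, sigma=1.0))
    # the edited miRNA is a highly expressed family member; give it a
    # sizeable share of the library so its hotspot is well covered
    abundances["hsa-miR-200b-3p"] = max(abundances["hsa-miR-200b-3p"], 10.0)
    return SimTruth(
        mirna_abundances=abundances,
        edit_fractions={("hsa-miR-200b-3p", 5): 0.01},
        per_base_error=per_base_error,
        group_effect=0.09,
        survival_beta=-0.8,
        seed=seed,
    )


def _validate_edit_sites(truth: SimTruth, refs: Sequence[MatureMiRNA]) -> None:
    by_id = {r.id: r for r in refs}
    for mid, pos in truth.edit_fractions:
        if mid not in by_id:
            raise ValueError(f"edit fraction assigned to unknown miRNA {mid}")
        seq = by_id[mid].sequence
        if not (1 <= pos <= len(seq)) or seq[pos - 1] != "A":
            raise ValueError(
                f"edit fraction assigned to non-A reference position {mid}:{pos}"
            )


def _phred_char(e: float) -> str:
    q = 41 if e <= 0 else min(41, int(round(-10 * math.log10(e))))
    return chr(q + 33)


def simulate_reads(
    truth: SimTruth,
    reference: Sequence[MatureMiRNA],
    n_reads: int,
    group: str,
    rng: np.random.Generator,
    read_length: int = 50,
    site_fraction_overrides: Mapping[tuple[str, int], float] | None = None,
) -> tuple[list[str], list[str]]:
    """Simulate one sample's reads; returns (sequences, qualities).

    Each read is a (possibly 5'-offset, 3'-trimmed) mature sequence with
    per-site A→G edits applied at the group's true fraction, uniform
    substitution errors at the per-base rate elsewhere, and the adapter
    appended; the whole molecule is truncated at the read length.
    ``site_fraction_overrides`` pins specific sites to a per-sample
    fraction (used to couple read-level editing to the clinical table).
    """
    if not reference:
        raise ValueError("reference panel must be non-empty")
    _validate_edit_sites(truth, reference)
    refs = [r for r in reference if truth.mirna_abundances.get(r.id, 0.0) > 0]
    weights = np.array([truth.mirna_abundances[r.id] for r in refs], dtype=float)
    weights /= weights.sum()
    offsets, off_p = zip(*sorted(truth.isomir_offsets.items()))
    trims, trim_p = zip(*sorted(truth.trim3_probs.items()))
    overrides = dict(site_fraction_overrides or {})
    edits_by_mirna: dict[str, list[tuple[int, float]]] = {}
    for (mid, pos), f in truth.edit_fractions.items():
        eff = truth.tumour_fraction((mid, pos)) if group == "tumour" else f
        eff = overrides.pop((mid, pos), eff)
        edits_by_mirna.setdefault(mid, []).append((pos, eff))
    for (mid, pos), eff in overrides.items():
        edits_by_mirna.setdefault(mid, []).append((pos, eff))
    e = truth.per_base_error
    qchar = _phred_char(e)
    adapter = _dna(truth.adapter)

    ref_idx = rng.choice(len(refs), size=n_reads, p=weights)
    off_idx = rng.choice(len(offsets), size=n_reads, p=np.array(off_p))
    trim_idx = rng.choice(len(trims), size=n_reads, p=np.array(trim_p))
    seqs, quals = [], []
    for i in range(n_reads):
        ref = refs[ref_idx[i]]
        offset = offsets[off_idx[i]]
        trim = trims[trim_idx[i]]
        mature = list(ref.sequence)
        for pos, f in edits_by_mirna.get(ref.id, ()):
            if f > 0 and rng.random() < f:
                mature[pos - 1] = "G"
        if offset >= 0:
            insert = mature[offset:]
        else:
            insert = list(rng.choice(_BASES, size=-offset)) + mature
        if trim:
            insert = insert[:-trim]
        if e > 0:
            for j in range(len(insert)):
                if rng.random() < e:
                    insert[j] = rng.choice([b for b in "ACGT" if b != insert[j]])
        read = ("".join(insert) + adapter)[:read_length]
        seqs.append(read)
        quals.append(qchar * len(read))
    return seqs, quals


def write_fastq(path: str | os.PathLike, seqs: Sequence[str], quals: Sequence[str], prefix: str) -> None:
    with open(path, "w") as fh:
        for i, (s, q) in enumerate(zip(seqs, quals), start=1):
            fh.write(f"@{prefix}_{i}\n{s}\n+\n{q}\n")


def simulate_counts(
    n_genes: int,
    n_samples_per_group: int,
    de_fraction: float,
    effect: float,
    truth: SimTruth,
    dispersion: float = 0.1,
    base_mean: float = 200.0,
    forced_down_genes: Sequence[str] = (),
    rng: np.random.Generator | None = None,
) -> tuple[CountMatrix, dict]:
    """Negative-binomial gene counts for a two-arm contrast (control vs
    edited-mimic), with the stated fraction of genes carrying the stated
    log2 fold change.  ``forced_down_genes`` are renamed genes guaranteed
    to be downregulated DE genes (the planted targets).

    Returns (CountMatrix, sidecar) where the sidecar records the DE flag
    and sign per gene, the dispersion, and the library size factors.
    """
    if n_genes < 1 or n_samples_per_group < 2:
        raise ValueError("need n_genes >= 1 and n >= 2 samples per group")
    if not (0.0 <= de_fraction <= 1.0):
        raise ValueError("de_fraction must lie in [0, 1]")
    rng = rng if rng is not None else np.random.default_rng([truth.seed, 202])
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    for i, g in enumerate(forced_down_genes):
        genes[i] = g
    n_de = int(round(de_fraction * n_genes))
    n_de = max(n_de, len(forced_down_genes))
    de_flags = np.zeros(n_genes, dtype=bool)
    de_flags[:n_de] = True
    signs = np.where(rng.random(n_genes) < 0.5, -1.0, 1.0)
    signs[: len(forced_down_genes)] = -1.0
    mu = rng.lognormal(mean=math.log(base_mean), sigma=1.0, size=n_genes)
    # planted targets emulate clearly expressed genes: keep them off the
    # low-count filter floor
    mu[: len(forced_down_genes)] = np.maximum(mu[: len(forced_down_genes)], base_mean)
    lib_factors = rng.uniform(0.7, 1.3, size=2 * n_samples_per_group)
    samples = [f"CTRL{i + 1:02d}" for i in range(n_samples_per_group)] + [
        f"ED{i + 1:02d}" for i in range(n_samples_per_group)
    ]
    groups = pd.Series(
        ["control"] * n_samples_per_group + ["edited"] * n_samples_per_group,
        index=samples,
    )
    mat = np.zeros((n_genes, 2 * n_samples_per_group), dtype=int)
    lfc = np.where(de_flags, signs * effect, 0.0)
    for j in range(2 * n_samples_per_group):
        m = mu * lib_factors[j]
        if groups.iloc[j] == "edited":
            m = m * np.power(2.0, lfc)
        # NB with dispersion phi: var = m + phi m^2
        shape = 1.0 / dispersion
        lam = rng.gamma(shape, m / shape)
        mat[:, j] = rng.poisson(lam)
    counts = pd.DataFrame(mat, index=genes, columns=samples)
    sidecar = {
        "de_genes": [g for g, flag in zip(genes, de_flags) if flag],
        "down_genes": [
            g for g, flag, s in zip(genes, de_flags, signs) if flag and s < 0
        ],
        "log2fc": dict(zip(genes, lfc.tolist())),
        "dispersion": dispersion,
        "lib_factors": dict(zip(samples, lib_factors.tolist())),
    }
    return CountMatrix(counts, groups), sidecar


def simulate_clinical(
    n_tumour: int,
    n_control: int,
    truth: SimTruth,
    level_sd_pct: float = 3.0,
    baseline_months: float = 36.0,
    censor_months: float = 84.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Clinical table plus per-sample editing level for the planted site.

    Editing levels (as %) are drawn around the group means implied by the
    truth; overall survival is exponential with log mean survival linear
    in the standardised editing level (slope ``survival_beta``), with
    administrative censoring; FIGO and the TNM M flag increase with the
    editing level plus noise.  Control samples carry no outcome data.
    """
    if n_tumour < 1 or n_control < 0:
        raise ValueError("need n_tumour >= 1 and n_control >= 0")
    if not math.isfinite(truth.survival_beta):
        raise ValueError("survival_beta must be finite")
    rng = rng if rng is not None else np.random.default_rng([truth.seed, 303])
    site = truth.differential_sites[0]
    f_ctl = 100.0 * truth.edit_fractions.get(site, 0.0)
    f_tum = 100.0 * truth.tumour_fraction(site)
    rows = []
    lvl_t = np.clip(rng.normal(f_tum, level_sd_pct, size=n_tumour), 0.0, 100.0)
    z = (lvl_t - lvl_t.mean()) / (lvl_t.std() if lvl_t.std() > 0 else 1.0)
    mean_surv = baseline_months * np.exp(truth.survival_beta * z)
    os_t = rng.exponential(mean_surv)
    event = (os_t <= censor_months).astype(int)
    os_obs = np.minimum(os_t, censor_months)
    figo_score = z + rng.normal(0.0, 1.0, size=n_tumour)
    figo = np.clip(np.digitize(figo_score, [-1.0, 0.0, 1.0]) + 1, 1, 4)
    m_prob = 1.0 / (1.0 + np.exp(-(z - 1.5)))
    tnm_m = (rng.random(n_tumour) < m_prob).astype(int)
    for i in range(n_tumour):
        rows.append(
            {
                "sample": f"T{i + 1:02d}",
                "group": "tumour",
                "os_months": round(float(os_obs[i]), 2),
                "event": int(event[i]),
                "figo": int(figo[i]),
                "tnm_m": int(tnm_m[i]),
                "editing_pct": round(float(lvl_t[i]), 3),
            }
        )
    lvl_c = np.clip(rng.normal(f_ctl, level_sd_pct / 3, size=n_control), 0.0, 100.0)
    for i in range(n_control):
        rows.append(
            {
                "sample": f"N{i + 1:02d}",
                "group": "control",
                "os_months": np.nan,
                "event": np.nan,
                "figo": np.nan,
                "tnm_m": np.nan,
                "editing_pct": round(float(lvl_c[i]), 3),
            }
        )
    return pd.DataFrame(rows)


def simulate_utrs(
    genes: Sequence[str],
    planted_sites: Mapping[str, int],
    ed_core: str = "CAGCATT",
    wt_core: str = "CAGTATT",
    length_range: tuple[int, int] = (250, 600),
    rng: np.random.Generator | None = None,
) -> dict[str, str]:
    """Random 3'UTRs free of both seed cores, with ``planted_sites[gene]``
    edited-seed 8mer sites inserted at spaced positions."""
    rng = rng if rng is not None else np.random.default_rng(404)
    utrs = {}
    for gene in genes:
        n_sites = planted_sites.get(gene, 0)
        for _ in range(200):
            length = int(rng.integers(*length_range))
            seq = "".join(rng.choice(_BASES, size=length))
            if ed_core in seq or wt_core in seq:
                continue
            if n_sites:
                gap = length // (n_sites + 1)
                chars = seq
                for k in range(1, n_sites + 1):
                    pos = k * gap
                    chars = chars[:pos] + ed_core + "A" + chars[pos:]
                seq = chars
                if seq.count(ed_core) != n_sites or wt_core in seq:
                    continue
            utrs[gene] = seq
            break
        else:  # pragma: no cover - rejection loop essentially never exhausts
            raise RuntimeError(f"could not generate a UTR for {gene}")
    return utrs


def simulate_qpcr(
    targets: Sequence[str],
    slopes: Mapping[str, float],
    ct_means: Mapping[str, Mapping[str, float]],
    noise_sd: float = 0.15,
    n_replicates: int = 3,
    roles: Mapping[str, str] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """qPCR runs: Ct values gaussian around the per-group means, one
    standard-curve slope per assay."""
    rng = rng if rng is not None else np.random.default_rng(505)
    roles = roles or {}
    rows = []
    for assay in targets:
        slope = slopes[assay]
        if slope >= 0:
            raise ValueError(f"assay {assay}: slope must be negative")
        for grp, mean_ct in ct_means[assay].items():
            for rep in range(1, n_replicates + 1):
                ct = mean_ct + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                rows.append(
                    {
                        "assay": assay,
                        "role": roles.get(assay, "target"),
                        "slope": slope,
                        "sample": f"{grp}_{rep}",
                        "group": grp,
                        "ct": round(float(ct), 4),
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class SyntheticBundle:
    """Paths to every generated input plus the ground-truth sidecar."""

    reads: dict[str, Path]  # sample id -> FASTQ path
    reference: Path
    blacklist: Path
    counts: Path
    clinical: Path
    utrs: Path
    predicted_targets: Path
    qpcr: Path
    truth_path: Path
    truth: SimTruth

    def sample_ids(self) -> list[str]:
        return list(self.reads)


def simulate_bundle(
    outdir: str | os.PathLike,
    seed: int = 0,
    n_tumour: int = 60,
    n_control: int = 48,
    reads_per_sample: int = 4000,
    n_genes: int = 400,
    de_fraction: float = 0.08,
    de_effect: float = 2.0,
    planted_targets: Mapping[str, int] | None = None,
    per_base_error: float = 0.001,
    truth: SimTruth | None = None,
) -> SyntheticBundle:
    """Generate the complete input set for one cohort.

    ``planted_targets`` maps gene symbols to the number of edited-seed
    binding sites planted in their 3'UTRs; these genes are simulated as
    downregulated under the edited mimic and included in the prediction
    list, so the candidate cascade should recover exactly them.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if truth is None:
        truth = default_truth(seed=seed, per_base_error=per_base_error)
    if planted_targets is None:
        planted_targets = {"MXI1": 3, "TSHZ3": 1, "OTX1": 2}
    refs = [MatureMiRNA(mid, seq) for mid, seq in DEFAULT_REFERENCE]

    ref_path = outdir / "reference.fa"
    with open(ref_path, "w") as fh:
        for mid, seq in DEFAULT_REFERENCE:
            fh.write(f">{mid}\n{seq}\n")
    blacklist_path = outdir / "blacklist.txt"
    blacklist_path.write_text("")  # none of the panel is repeat-derived

    clin = simulate_clinical(
        n_tumour, n_control, truth, rng=np.random.default_rng([seed, 303])
    )
    clinical_path = outdir / "clinical.csv"
    clin.to_csv(clinical_path, index=False)

    reads_dir = outdir / "reads"
    reads_dir.mkdir(exist_ok=True)
    fastqs: dict[str, Path] = {}
    site = truth.differential_sites[0]
    for k, row in enumerate(clin.itertuples()):
        rng = np.random.default_rng([seed, 1000 + k])
        # reads reflect the same per-sample editing level the clinical
        # outcome was generated from
        seqs, quals = simulate_reads(
            truth,
            refs,
            reads_per_sample,
            row.group,
            rng,
            site_fraction_overrides={site: row.editing_pct / 100.0},
        )
        path = reads_dir / f"{row.sample}.fastq"
        write_fastq(path, seqs, quals, row.sample)
        fastqs[row.sample] = path

    decoys = {"F3": 0, "RAB5C": 0}  # predicted + down but no ED site
    forced_down = list(planted_targets) + list(decoys)
    cm, de_sidecar = simulate_counts(
        n_genes,
        max(4, min(10, n_tumour // 6)),
        de_fraction,
        de_effect,
        truth,
        forced_down_genes=forced_down,
        rng=np.random.default_rng([seed, 202]),
    )
    counts_path = outdir / "counts.tsv"
    cm.counts.to_csv(counts_path, sep="\t")
    (outdir / "counts_groups.tsv").write_text(
        "sample\tgroup\n"
        + "".join(f"{s}\t{g}\n" for s, g in cm.groups.items())
    )

    utr_rng = np.random.default_rng([seed, 404])
    gene_list = list(cm.counts.index)
    utrs = simulate_utrs(gene_list, dict(planted_targets), rng=utr_rng)
    utr_path = outdir / "utrs.fa"
    with open(utr_path, "w") as fh:
        for gene in gene_list:
            fh.write(f">{gene}\n{utrs[gene]}\n")

    pred_rng = np.random.default_rng([seed, 606])
    pred_rows = []
    for gene in planted_targets:
        pred_rows.append((gene, float(pred_rng.uniform(70, 100))))
    for gene in decoys:
        pred_rows.append((gene, float(pred_rng.uniform(50, 80))))
    # predicted decoys that are not differentially expressed
    for gene in gene_list[len(forced_down) : len(forced_down) + 5]:
        pred_rows.append((gene, float(pred_rng.uniform(50, 70))))
    pred_path = outdir / "predicted_targets.tsv"
    with open(pred_path, "w") as fh:
        fh.write("gene\tscore\n")
        for gene, score in sorted(pred_rows):
            fh.write(f"{gene}\t{score:.1f}\n")

    qpcr_df = simulate_qpcr(
        targets=["miR-200b-ED", "miR-200b-WT", "hsa-miR-103a-3p", "hsa-miR-199b-5p"],
        slopes={
            "miR-200b-ED": -3.3219,
            "miR-200b-WT": -3.3219,
            "hsa-miR-103a-3p": -3.4,
            "hsa-miR-199b-5p": -3.25,
        },
        ct_means={
            # ADAR1 knockdown halves the edited species only
            "miR-200b-ED": {"siADAR1": 26.0, "siNEG": 25.0},
            "miR-200b-WT": {"siADAR1": 22.0, "siNEG": 22.0},
            "hsa-miR-103a-3p": {"siADAR1": 20.0, "siNEG": 20.0},
            "hsa-miR-199b-5p": {"siADAR1": 21.0, "siNEG": 21.0},
        },
        roles={"hsa-miR-103a-3p": "reference", "hsa-miR-199b-5p": "reference"},
        rng=np.random.default_rng([seed, 505]),
    )
    qpcr_path = outdir / "qpcr.csv"
    qpcr_df.to_csv(qpcr_path, index=False)

    truth_path = outdir / "truth.json"
    truth.to_json(truth_path)
    sidecar_path = outdir / "de_truth.json"
    sidecar_path.write_text(json.dumps(de_sidecar, indent=2, sort_keys=True))

    return SyntheticBundle(
        reads=fastqs,
        reference=ref_path,
        blacklist=blacklist_path,
        counts=counts_path,
        clinical=clinical_path,
        utrs=utr_path,
        predicted_targets=pred_path,
        qpcr=qpcr_path,
        truth_path=truth_path,
        truth=truth,
    )
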