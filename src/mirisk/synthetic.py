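"""Synthetic miRNA-seq cohorts with planted group effects and correlation.

The generator emulates the statistical structure the downstream analysis
assumes: a three-group cohort (unaffected comparison subjects, clinical
high-risk subjects who did not progress to psychosis, and high-risk
subjects who did), negative-binomial read counts on a log-normal latent
mean, a per-sample multiplicative library-size factor, a handful of
planted group-shifted miRNAs, and a tunable within-group miRNA-miRNA
correlation induced by a single shared latent factor per sample.

Counts for miRNA *i* in sample *s* of group *g* are drawn as::

    latent_is = rho_g * F_s + sqrt(1 - rho_g**2) * eps_is
    log mu_is = log(base_i) + sigma * latent_is + delta_ig + log(L_s)
    count_is ~ NegBin(mean=mu_is, dispersion=alpha)

where ``F_s`` and ``eps_is`` are iid standard normals, ``sigma`` is the
biological log-scale s.d. and ``L_s`` is the library-size factor sampled
log-uniformly.  Because the library factor is multiplicative on every
miRNA of a sample, top-k quotient normalization removes it exactly.

``rho_g`` is the signed per-miRNA factor weight ``lambda_i *
sqrt(strength_g)``, where ``lambda_i`` is a Rademacher (+/-1) loading
sign fixed per miRNA and ``strength_g`` is the group's correlation
strength: pairs of equally-loaded miRNAs then correlate at approximately
``+strength_g`` and opposite pairs at ``-strength_g`` on the latent
scale.  The loading signs matter: a factor hitting every miRNA of a
sample identically is indistinguishable from library size and would be
cancelled exactly by quotient normalization, leaving no correlation for
the network stage to find.  Planted miRNAs carry no factor loading, so
their group effect stays uncontaminated.

Planted effects are stated in reference-group s.d. units, i.e. as the
standardized (pooled-s.d.) group difference the downstream analysis
observes.  A multiplicative count model cannot realize that with a naive
log shift — scaling the mean also scales the s.d. — so the planted
log-shift ``delta_ig = sign * log(u)`` is calibrated in closed form::

    c = (effect * CV)**2 / 2,   u = (1 + sqrt(c * (2 - c))) / (1 - c)

where ``CV = sqrt((1 + alpha) * exp(sigma**2) - 1)`` is the
coefficient of variation of a count around its sample's scale.  This
makes up- and down-regulated markers equally detectable (the pooled
standardized difference is invariant under ``u -> 1/u``) and requires
``effect * CV < sqrt(2)``, the largest standardized difference a
multiplicative shift can produce.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from mirisk.quantify import MatureMirna

GROUPS = ("unaffected", "nonprogressed", "progressed")

_RNA = "ACGU"


class ConfigurationError(ValueError):
    """Raised when a cohort or read configuration violates its invariants."""


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic three-group miRNA-seq cohort.

    Defaults mirror the study design this package targets: 27 unaffected,
    37 nonprogressed and 30 progressed subjects over 136 robustly
    expressed miRNAs, with five planted risk markers (three down, two up
    in the progressed group) and strong miRNA co-regulation in the
    unaffected/nonprogressed groups but weak co-regulation in the
    progressed group.
    """

    n_unaffected: int = 27
    n_nonprogressed: int = 37
    n_progressed: int = 30
    n_mirnas: int = 136
    #: (miRNA index, sign in {+1,-1}, effect size in biological-s.d. units)
    planted: tuple[tuple[int, int, float], ...] = (
        (7, -1, 1.2),
        (23, -1, 1.2),
        (58, -1, 1.2),
        (91, +1, 1.2),
        (120, +1, 1.2),
    )
    dispersion: float = 0.01
    library_size_range: tuple[float, float] = (0.5, 2.0)
    correlation_strength: Mapping[str, float] = field(
        default_factory=lambda: {
            "unaffected": 0.85,
            "nonprogressed": 0.85,
            "progressed": 0.30,
        }
    )
    #: biological log-scale s.d. of each miRNA across subjects
    #: (between-subject CV ~ 35% together with the default dispersion)
    biological_sd: float = 0.3
    #: fraction of high-risk (nonprogressed/progressed) subjects flagged
    #: as medicated, independent of expression
    medicated_fraction: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_unaffected", "n_nonprogressed", "n_progressed"):
            if getattr(self, name) < 2:
                raise ConfigurationError(f"{name} must be >= 2, got {getattr(self, name)}")
        if self.n_mirnas < 1:
            raise ConfigurationError(f"n_mirnas must be >= 1, got {self.n_mirnas}")
        idx = [p[0] for p in self.planted]
        if len(set(idx)) != len(idx):
            raise ConfigurationError("planted: miRNA indices must be distinct")
        for i, sign, effect in self.planted:
            if not 0 <= i < self.n_mirnas:
                raise ConfigurationError(f"planted: index {i} out of range [0, {self.n_mirnas})")
            if sign not in (+1, -1):
                raise ConfigurationError(f"planted: sign must be +1 or -1, got {sign}")
            if not math.isfinite(effect):
                raise ConfigurationError(f"planted: effect for index {i} is not finite")
            cv = _count_cv(self.biological_sd, self.dispersion)
            if abs(effect) * cv >= math.sqrt(2.0):
                raise ConfigurationError(
                    f"planted: |effect|={abs(effect)} unrealizable; a multiplicative "
                    f"shift cannot exceed sqrt(2)/CV = {math.sqrt(2.0) / cv:.2f} "
                    "standardized units at these noise settings"
                )
        if not self.dispersion > 0:
            raise ConfigurationError(f"dispersion must be > 0, got {self.dispersion}")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ConfigurationError(f"library_size_range must satisfy 0 < min <= max, got {self.library_size_range}")
        for g in GROUPS:
            rho = self.correlation_strength.get(g, 0.0)
            if not 0 <= rho < 1:
                raise ConfigurationError(f"correlation_strength[{g}] must be in [0, 1), got {rho}")
        if not self.biological_sd > 0:
            raise ConfigurationError(f"biological_sd must be > 0, got {self.biological_sd}")
        if not 0 <= self.medicated_fraction <= 1:
            raise ConfigurationError(f"medicated_fraction must be in [0, 1], got {self.medicated_fraction}")


@dataclass
class SyntheticCohort:
    """A generated cohort: counts, sample metadata, and ground truth."""

    counts: pd.DataFrame  # miRNA x sample, nonnegative integers
    metadata: pd.DataFrame  # columns: sample_id, group, medicated
    truth: dict

    def write(self, counts_path, metadata_path, truth_path=None) -> None:
        """Serialize counts as TSV, metadata as CSV and truth as JSON."""
        self.counts.to_csv(counts_path, sep="\t", index_label="mirna")
        self.metadata.to_csv(metadata_path, index=False)
        if truth_path is not None:
            import json

            with open(truth_path, "w") as fh:
                json.dump(self.truth, fh, indent=1, sort_keys=True)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a synthetic cohort with planted effects and correlations.

    Deterministic for a fixed ``config.seed``.  Planted miRNAs have their
    log-mean shifted by ``sign * effect * biological_sd`` in the
    progressed group relative to the other two groups.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    m = config.n_mirnas
    sizes = {
        "unaffected": config.n_unaffected,
        "nonprogressed": config.n_nonprogressed,
        "progressed": config.n_progressed,
    }
    n_total = sum(sizes.values())

    # Baseline abundances emulate robustly-expressed miRNAs: log-normal
    # across miRNAs with a floor so every row would survive a
    # 10 000-total-read robustness filter at these cohort sizes.
    base_log = rng.normal(math.log(500.0), 1.2, size=m)
    base_log = np.maximum(base_log, math.log(150.0))

    lo, hi = config.library_size_range
    lib = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n_total))

    sigma = config.biological_sd
    cv = _count_cv(sigma, config.dispersion)
    shift = np.zeros(m)
    for i, sign, effect in config.planted:
        shift[i] = sign * _calibrated_log_shift(abs(effect), cv) * (1 if effect >= 0 else -1)

    mirna_ids = [f"syn-miR-{i:03d}" for i in range(m)]
    # Rademacher loading signs, zeroed for planted miRNAs so the factor
    # never contaminates the planted group effects.
    loadings = rng.choice([-1.0, 1.0], size=m)
    for i, _, _ in config.planted:
        loadings[i] = 0.0

    sample_ids: list[str] = []
    groups: list[str] = []
    cols = []
    s_ofs = 0
    for g in GROUPS:
        strength = float(config.correlation_strength.get(g, 0.0))
        weight = loadings * math.sqrt(strength)
        resid = np.sqrt(1.0 - weight * weight)
        for k in range(sizes[g]):
            sid = f"{g[:2].upper()}{k:03d}"
            sample_ids.append(sid)
            groups.append(g)
            factor = rng.normal()
            eps = rng.normal(size=m)
            latent = weight * factor + resid * eps
            log_mu = base_log + sigma * latent + math.log(lib[s_ofs])
            if g == "progressed":
                log_mu = log_mu + shift
            mu = np.exp(log_mu)
            r = 1.0 / config.dispersion
            p = r / (r + mu)
            cols.append(rng.negative_binomial(r, p))
            s_ofs += 1

    counts = pd.DataFrame(
        np.column_stack(cols), index=mirna_ids, columns=sample_ids, dtype=np.int64
    )
    medicated = np.zeros(n_total, dtype=int)
    hr = np.array([g != "unaffected" for g in groups])
    medicated[hr] = (rng.random(hr.sum()) < config.medicated_fraction).astype(int)
    metadata = pd.DataFrame(
        {"sample_id": sample_ids, "group": groups, "medicated": medicated}
    )
    truth = {
        "planted": [
            {"mirna": mirna_ids[i], "index": i, "sign": sign, "effect": effect}
            for i, sign, effect in config.planted
        ],
        "correlation_strength": {g: float(config.correlation_strength.get(g, 0.0)) for g in GROUPS},
        "factor_loadings": loadings.astype(int).tolist(),
        "seed": config.seed,
    }
    return SyntheticCohort(counts=counts, metadata=metadata, truth=truth)


def _count_cv(sigma: float, dispersion: float) -> float:
    """Coefficient of variation of a count around its sample's scale.

    Combines the biological log-normal spread with negative-binomial
    overdispersion; the Poisson term 1/mu is negligible at the abundances
    the generator emulates and is omitted.
    """
    return math.sqrt((1.0 + dispersion) * math.exp(sigma * sigma) - 1.0)


def _calibrated_log_shift(effect: float, cv: float) -> float:
    """Log-scale shift realizing a standardized group difference ``effect``.

    Solves (u - 1) / (cv * sqrt((1 + u**2) / 2)) = effect for u = exp(delta);
    the solution is symmetric under u -> 1/u, so up- and down-regulated
    markers are equally detectable.
    """
    if effect == 0:
        return 0.0
    c = (effect * cv) ** 2 / 2.0
    u = (1.0 + math.sqrt(c * (2.0 - c))) / (1.0 - c)
    return math.log(u)


def generate_technical_duplicate(
    cohort: SyntheticCohort, sample_id: str, noise_sd: float, seed: int
) -> pd.Series:
    """A technical-duplicate count column for one sample.

    Log-counts of the duplicate equal the original's plus iid normal noise
    of s.d. ``noise_sd``, rounded back to nonnegative integers (zero
    counts stay zero).  ``noise_sd = 0`` reproduces the column exactly.
    """
    if noise_sd < 0:
        raise ConfigurationError(f"noise_sd must be >= 0, got {noise_sd}")
    if sample_id not in cohort.counts.columns:
        raise KeyError(f"unknown sample id: {sample_id!r}")
    rng = np.random.default_rng(seed)
    col = cohort.counts[sample_id].to_numpy(dtype=float)
    noise = rng.normal(0.0, noise_sd, size=col.size) if noise_sd > 0 else np.zeros(col.size)
    dup = np.rint(col * np.exp(noise))
    dup = np.maximum(dup, 0).astype(np.int64)
    return pd.Series(dup, index=cohort.counts.index, name=f"{sample_id}-dup")


def generate_reads(
    mirnas: Sequence[MatureMirna],
    abundances: Sequence[float],
    n_reads: int,
    read_length: int,
    seed: int,
    max_rejections: int = 1000,
) -> list[SeqRecord]:
    """Simulate reads each embedding exactly one mature miRNA sequence.

    Each read carries one miRNA (sampled proportionally to ``abundances``)
    at a uniform random offset, padded with random bases.  Flanking bases
    are rejection-sampled so that no read accidentally contains a second
    exact match to any miRNA in the panel.  Returns FASTQ-serializable
    records with constant quality 'I' (Phred 40).
    """
    if len(mirnas) != len(abundances):
        raise ConfigurationError("mirnas and abundances must have equal length")
    ab = np.asarray(abundances, dtype=float)
    if ab.size and (ab < 0).any():
        raise ConfigurationError("abundances must be nonnegative")
    if n_reads > 0 and (ab.size == 0 or ab.sum() == 0):
        raise ConfigurationError("abundances must not be all zero")
    longest = max((len(m.sequence) for m in mirnas), default=0)
    if read_length < longest:
        raise ConfigurationError(
            f"read_length {read_length} shorter than longest miRNA ({longest} nt)"
        )
    rng = np.random.default_rng(seed)
    probs = ab / ab.sum() if n_reads > 0 else ab
    seqs = [m.sequence for m in mirnas]
    records: list[SeqRecord] = []
    for ridx in range(n_reads):
        which = int(rng.choice(len(seqs), p=probs))
        insert = seqs[which]
        for _ in range(max_rejections):
            offset = int(rng.integers(0, read_length - len(insert) + 1))
            left = "".join(rng.choice(list(_RNA), size=offset))
            right = "".join(rng.choice(list(_RNA), size=read_length - offset - len(insert)))
            read = left + insert + right
            if _occurrences(read, insert) == 1 and all(
                _occurrences(read, s) == 0 for s in seqs if s != insert
            ):
                break
        else:  # pragma: no cover - astronomically unlikely with sane panels
            raise RuntimeError("could not place flanking bases without a spurious match")
        rec = SeqRecord(
            Seq(read),
            id=f"read{ridx:06d}|{mirnas[which].id}",
            description="",
        )
        rec.letter_annotations["phred_quality"] = [40] * read_length
        records.append(rec)
    return records


def _occurrences(text: str, pattern: str) -> int:
    """Count (possibly overlapping) occurrences of pattern in text."""
    count = start = 0
    while True:
        start = text.find(pattern, start)
        if start == -1:
            return count
        count += 1
        start += 1
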