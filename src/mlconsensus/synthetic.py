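"""Synthetic species datasets with a planted core motif.

The generator emulates the shape of curated binding-site collections:
every factor has one core pattern present (in part or whole, with
per-position noise) in each of its sites, surrounded by random flanks, and
site lengths vary widely — the defaults target a mean site length of about
12 with a standard deviation of about 6, the scale typical of curated
TFBS databases.  Flank length is drawn as a single negative-binomial total
(the overdispersed generalisation of a geometric draw, solved in closed
form from the target mean/variance to reproduce the long right tail of
real length spreads) and split binomially between the two sides.

A truth record accompanies every dataset: the per-factor core and each
site's core span, enabling core-recovery checks without external data.
All randomness flows through one seeded generator, so datasets are
byte-reproducible from the spec.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .consensus import BASES, SYMBOL_COVERAGE
from .seqio import SiteRecord, SiteSet, SpeciesDataset


@dataclass
class SynthSpec:
    """Parameters of the synthetic species generator.

    ``core_conservation`` is the per-position probability that a site emits
    the core base (off-bases are uniform over the other three);
    ``core_truncation_prob`` is the chance a site carries the core only in
    part (a uniform-length prefix or suffix is removed).  ``mean_length``
    and ``sd_length`` steer the *site* length distribution; the per-factor
    SD/mean length-variability ratio this induces is reportable via
    :func:`variability_histogram`.
    """

    n_tfs: int = 20
    sites_per_tf: int = 8
    core_length: int = 6
    core_conservation: float = 0.9
    mean_length: float = 12.0
    sd_length: float = 6.0
    core_truncation_prob: float = 0.0
    background: tuple = (0.25, 0.25, 0.25, 0.25)
    species: str = "synthetic"
    seed: int | None = None

    def validate(self) -> None:
        if self.n_tfs < 1 or self.sites_per_tf < 1:
            raise ValueError("n_tfs and sites_per_tf must be positive")
        if self.sites_per_tf < 3:
            warnings.warn("fewer than 3 sites per TF: sets will fail the LOOCV admission rule")
        if self.core_length < 1:
            raise ValueError("core_length must be >= 1")
        if not 0.0 <= self.core_conservation <= 1.0:
            raise ValueError("core_conservation must lie in [0, 1]")
        if not 0.0 <= self.core_truncation_prob <= 1.0:
            raise ValueError("core_truncation_prob must lie in [0, 1]")
        if self.mean_length < self.core_length:
            raise ValueError(
                f"impossible spec: mean_length {self.mean_length} below "
                f"core_length {self.core_length}"
            )
        if self.sd_length < 0:
            raise ValueError("sd_length must be non-negative")
        if len(self.background) != 4 or abs(sum(self.background) - 1.0) > 1e-9:
            raise ValueError("background must be 4 frequencies summing to 1")


def _flank_sampler(spec: SynthSpec):
    """Closed-form fit of the total-flank distribution to the target
    site-length mean/variance (all variance is carried by the flanks)."""
    m = spec.mean_length - spec.core_length
    v = spec.sd_length**2
    if m == 0:
        return lambda rng: 0
    if v > m:  # overdispersed: negative binomial (geometric-tailed)
        p = m / v
        r = m * m / (v - m)
        return lambda rng: int(rng.negative_binomial(r, p))
    if v == m:
        return lambda rng: int(rng.poisson(m))
    # underdispersed: binomial with matched first two moments
    n_trials = max(1, int(round(m * m / (m - v))))
    return lambda rng: int(rng.binomial(n_trials, min(1.0, m / n_trials)))


def _random_seq(rng: np.random.Generator, length: int, background) -> str:
    if length == 0:
        return ""
    return "".join(rng.choice(list(BASES), size=length, p=list(background)))


def generate_dataset(spec: SynthSpec) -> tuple[SpeciesDataset, dict]:
    """Generate a species dataset and its truth record.

    Truth record layout::

        {"species": ..., "spec": {...}, "tfs": {tf_id: {"core": str,
         "sites": {site_id: {"core_start": int, "core_end": int,
                             "core_fragment": str}}}}}

    Spans are 1-based inclusive positions within the site sequence.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    draw_flank = _flank_sampler(spec)
    bases = list(BASES)
    records: list[SiteRecord] = []
    truth: dict = {
        "species": spec.species,
        "spec": {k: v for k, v in vars(spec).items() if k != "background"},
        "tfs": {},
    }
    for t in range(spec.n_tfs):
        tf_id = f"TF{t + 1:03d}"
        core = _random_seq(rng, spec.core_length, (0.25,) * 4)
        tf_truth: dict = {"core": core, "sites": {}}
        for s in range(spec.sites_per_tf):
            site_id = f"{tf_id}_s{s + 1}"
            fragment = core
            if spec.core_length > 1 and rng.random() < spec.core_truncation_prob:
                cut = int(rng.integers(1, spec.core_length))
                fragment = fragment[cut:] if rng.random() < 0.5 else fragment[:-cut]
            noised = []
            for b in fragment:
                if rng.random() < spec.core_conservation:
                    noised.append(b)
                else:
                    noised.append(bases[(bases.index(b) + int(rng.integers(1, 4))) % 4])
            fragment = "".join(noised)
            total_flank = draw_flank(rng)
            left = int(rng.binomial(total_flank, 0.5))
            right = total_flank - left
            seq = (
                _random_seq(rng, left, spec.background)
                + fragment
                + _random_seq(rng, right, spec.background)
            )
            if not seq:  # fully truncated core with no flanks; keep one base
                seq = _random_seq(rng, 1, spec.background)
            records.append(
                SiteRecord(site_id=site_id, tf_id=tf_id, species=spec.species, sequence=seq)
            )
            tf_truth["sites"][site_id] = {
                "core_start": left + 1,
                "core_end": left + len(fragment),
                "core_fragment": fragment,
            }
        truth["tfs"][tf_id] = tf_truth
    return SpeciesDataset.from_records(spec.species, records), truth


_FIG_BINS = [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, np.inf]


def variability_histogram(dataset: SpeciesDataset) -> pd.DataFrame:
    """Per-factor SD/mean length-variability ratios, binned.

    The ratio uses the population standard deviation of a factor's site
    lengths.  Bins span 0..0.6 in steps of 0.1 plus an overflow bin; the
    columns give the fraction of factors and of sites in each bin.
    """
    ratios, weights = [], []
    for site_set in dataset:
        if len(site_set) == 0:
            warnings.warn(f"excluding empty TF {site_set.tf_id!r}")
            continue
        lengths = np.array([len(s) for s in site_set.sequences], dtype=float)
        ratios.append(lengths.std() / lengths.mean())
        weights.append(len(site_set))
    if not ratios:
        raise ValueError("dataset holds no non-empty factors")
    ratios = np.array(ratios)
    weights = np.array(weights, dtype=float)
    rows = []
    for lo, hi in zip(_FIG_BINS[:-1], _FIG_BINS[1:]):
        in_bin = (ratios >= lo) & (ratios < hi)
        rows.append(
            {
                "bin_low": lo,
                "bin_high": hi,
                "tf_fraction": in_bin.mean(),
                "bs_fraction": weights[in_bin].sum() / weights.sum(),
            }
        )
    return pd.DataFrame(rows)


def consensus_contains_core(consensus_string: str, core: str) -> bool:
    """True when some consensus window covers the core base-for-base
    (ambiguity codes generalise; gaps do not cover anything)."""
    n, w = len(consensus_string), len(core)
    for start in range(0, n - w + 1):
        window = consensus_string[start : start + w]
        if all(b in SYMBOL_COVERAGE[c] for c, b in zip(window, core)):
            return True
    return False
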