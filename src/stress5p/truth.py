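"""Ground-truth binding model for the CRAC simulator.

Each transcript carries two occupancy components for a scanning initiation
factor: a 5'-end component (5'UTR plus the first 150 nt of CDS, the region
where 43S recruitment and scanning occur) and a pervasive component spread
along the whole transcript body (the Ded1-like pattern).  Stress is modeled
as per-condition *retention* factors in [0, 1] applied to each component:
glucose withdrawal ablates 5' binding within 30 s (retention ~0.1 from the
first time point onward), while heat shock erodes it progressively over
~16 min.

The expected probability that a sequenced crosslink comes from transcript t
under condition c is

    p_t(c)  proportional to  abundance_t(c) * (fw_t * fr(c) + pw_t * pr(c)),

renormalized over all transcripts.  rRNA-like background loci are treated as
stress-insensitive (effective retentions 1): ribosomes neither dissolve nor
lose rRNA contacts on these time scales, which is what makes the background
usable as an internal normalization standard.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeBundle

#: condition -> (fivep_retention, pervasive_retention)
DEFAULT_RETENTION: dict[str, tuple[float, float]] = {
    "control": (1.0, 1.0),
    "mock": (1.0, 1.0),
    "glucose_30s": (0.1, 1.0),
    "glucose_16min": (0.1, 1.0),
    "heat_16min": (0.2, 0.5),
    # cycloheximide co-treatment stabilizes mRNAs but does not restore
    # scanning-factor 5' binding
    "heat_cyh_16min": (0.2, 0.5),
}

#: condition -> regulon -> mRNA abundance multiplier (decay model)
DEFAULT_DECAY: dict[str, dict[str, float]] = {
    "control": {"RP": 1.0, "RiBi": 1.0, "other": 1.0},
    "mock": {"RP": 1.0, "RiBi": 1.0, "other": 1.0},
    "glucose_30s": {"RP": 1.0, "RiBi": 1.0, "other": 1.0},
    "glucose_16min": {"RP": 1 / 2.5, "RiBi": 1 / 2.5, "other": 0.9},
    "heat_16min": {"RP": 1 / 16, "RiBi": 1 / 16, "other": 0.9},
    "heat_cyh_16min": {"RP": 1.0, "RiBi": 1.0, "other": 1.0},
}


@dataclass
class StressModel:
    """Per-condition component retentions and regulon decay multipliers."""

    retention: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_RETENTION))
    decay: dict[str, dict[str, float]] = field(default_factory=lambda: dict(DEFAULT_DECAY))

    def __post_init__(self) -> None:
        for cond, (fr, pr) in self.retention.items():
            if not (0 <= fr <= 1 and 0 <= pr <= 1):
                raise ValueError(f"{cond}: retentions must lie in [0, 1]")

    def abundance_multiplier(self, condition: str, regulon: str) -> float:
        table = self.decay.get(condition, {})
        return table.get(regulon, table.get("other", 1.0))


@dataclass
class BindingTruth:
    """Planted binding weights, retentions and abundances.

    ``weights`` maps transcript id -> (fivep_weight, pervasive_weight);
    ``abundance`` is a DataFrame indexed by transcript id with one column per
    condition; ``stress_sensitive`` marks transcripts whose components are
    scaled by the condition retentions (mRNAs; rRNA background is immune).
    """

    weights: pd.DataFrame  # columns: fivep_weight, pervasive_weight
    retention: dict[str, tuple[float, float]]
    abundance: pd.DataFrame
    stress_sensitive: pd.Series
    pervasive_planted: pd.Series  # bool: Ded1-like transcripts by construction

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.weights.index)

    def conditions(self) -> list[str]:
        return list(self.retention)

    def effective_retention(self, condition: str) -> pd.DataFrame:
        """Per-transcript (fivep, pervasive) retention under ``condition``."""
        fr, pr = self.retention[condition]
        sens = self.stress_sensitive.astype(float)
        return pd.DataFrame(
            {
                "fivep": fr * sens + (1 - sens),
                "pervasive": pr * sens + (1 - sens),
            },
            index=self.weights.index,
        )

    def component_mass(self, condition: str) -> pd.DataFrame:
        """Unnormalized expected read mass per transcript and component."""
        eff = self.effective_retention(condition)
        a = self.abundance[condition]
        return pd.DataFrame(
            {
                "fivep": a * self.weights["fivep_weight"] * eff["fivep"],
                "pervasive": a * self.weights["pervasive_weight"] * eff["pervasive"],
            }
        )

    def read_probabilities(self, condition: str) -> pd.Series:
        """Per-transcript read probability (sums to 1)."""
        mass = self.component_mass(condition).sum(axis=1)
        total = mass.sum()
        if total <= 0:
            raise ValueError(f"no binding mass under condition {condition!r}")
        return mass / total

    def fivep_fraction(self, transcript_id: str, condition: str) -> float:
        """Probability that a read from this transcript comes from the 5' component."""
        m = self.component_mass(condition).loc[transcript_id]
        tot = m["fivep"] + m["pervasive"]
        return 0.0 if tot == 0 else float(m["fivep"] / tot)

    def expected_fivep_share(self, condition: str) -> float:
        """Expected fraction of all reads drawn from 5' components."""
        m = self.component_mass(condition)
        return float(m["fivep"].sum() / m.to_numpy().sum())


def make_binding_truth(
    bundle: GenomeBundle,
    factor_profile: dict | None = None,
    stress_model: StressModel | None = None,
    seed: int = 0,
) -> BindingTruth:
    """Plant a binding ground truth on a genome bundle.

    ``factor_profile`` keys (all optional):

    - ``fivep_share`` (default 0.9): 5' occupancy share of eIF4B-like transcripts.
    - ``pervasive_transcript_fraction`` (default 0.0): fraction of study mRNAs
      given a Ded1-like pervasive profile.
    - ``pervasive_fivep_share`` (default 0.2): 5' share for Ded1-like
      transcripts (must keep pervasive_weight >= fivep_weight).
    - ``background_share`` (default 0.5 if rRNA loci exist, else 0): share of
      total control binding assigned to rRNA-like background loci.
    """
    if not bundle.transcripts:
        raise ValueError("empty bundle")
    profile = dict(factor_profile or {})
    fivep_share = float(profile.get("fivep_share", 0.9))
    perv_frac = float(profile.get("pervasive_transcript_fraction", 0.0))
    perv_fivep_share = float(profile.get("pervasive_fivep_share", 0.2))
    if not 0 <= fivep_share <= 1 or not 0 <= perv_frac <= 1:
        raise ValueError("factor profile fractions must lie in [0, 1]")
    if perv_fivep_share > 0.5:
        raise ValueError("pervasive profile must satisfy pervasive_weight >= fivep_weight")
    model = stress_model or StressModel()
    rng = np.random.default_rng(seed)

    mrnas = [t for t in bundle.study_transcripts if t.biotype == "mRNA"]
    background = bundle.background_transcripts
    spikes = bundle.spike_transcripts
    if not mrnas:
        raise ValueError("bundle has no study mRNA transcripts")
    bg_share = float(profile.get("background_share", 0.5 if background else 0.0))
    if bg_share and not background:
        raise ValueError("background_share > 0 but bundle has no rRNA-like loci")

    n_perv = int(round(perv_frac * len(mrnas)))
    perv_idx = set(rng.choice(len(mrnas), size=n_perv, replace=False).tolist()) if n_perv else set()

    ids, fw, pw, sens, perv = [], [], [], [], []
    for i, t in enumerate(mrnas):
        share = perv_fivep_share if i in perv_idx else fivep_share
        ids.append(t.id)
        fw.append(share)
        pw.append(1.0 - share)
        sens.append(True)
        perv.append(i in perv_idx)
    if background:
        # total background weight = bg_share / (1 - bg_share) * total mRNA weight
        w_bg = bg_share / (1.0 - bg_share) * len(mrnas) / len(background) if bg_share else 0.0
        for t in background:
            ids.append(t.id)
            fw.append(0.0)
            pw.append(w_bg)
            sens.append(False)
            perv.append(True)
    for t in spikes:
        ids.append(t.id)
        fw.append(0.0)
        pw.append(0.0)  # the spike species is not crosslinked to the tagged factor
        sens.append(False)
        perv.append(False)

    weights = pd.DataFrame({"fivep_weight": fw, "pervasive_weight": pw}, index=pd.Index(ids, name="transcript"))
    regulon = {t.id: t.regulon for t in bundle.transcripts}
    abundance = pd.DataFrame(
        {
            cond: [
                model.abundance_multiplier(cond, regulon[tid]) if tid in {t.id for t in mrnas} else 1.0
                for tid in ids
            ]
            for cond in model.retention
        },
        index=weights.index,
    )
    return BindingTruth(
        weights=weights,
        retention=dict(model.retention),
        abundance=abundance,
        stress_sensitive=pd.Series(sens, index=weights.index),
        pervasive_planted=pd.Series(perv, index=weights.index),
    )
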