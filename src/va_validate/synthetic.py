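"""Synthetic gold-standard VA data with a known probbase.

The generator emulates the structure of a multi-site gold-standard VA
validation database: a fixed cause list per age module, a binary symptom
battery on the order of 100-200 items, cause-conditional symptom endorsement,
symmetric reporting noise, completely-at-random missingness and uniform site
assignment.  Because the generating probbase and cause composition are known,
every downstream stage (probbase estimation, classification, the split /
resample protocol, the accuracy metrics) can be tested end-to-end without any
external download.

The cause-symptom structure is a signature model: each cause owns a small
block of dedicated "signature" symptoms endorsed with probability
``signature_strength``; all other symptoms are endorsed at a common
``background_rate``.  This is a deliberate idealisation — real VA items are
shared across causes with graded propensities — but it gives a single knob
(strength vs. background vs. flip noise) for how separable causes are.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datamodel import (
    MISSING,
    MODULES,
    CauseList,
    Probbase,
    SymptomDictionary,
    VADataset,
    default_cause_list,
)

__all__ = ["GeneratorConfig", "generate_probbase", "generate_dataset", "phmrc_like_preset"]


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic VA data-generating process.

    csmf_true
        True cause composition the gold causes are drawn from (uniform when
        omitted).
    signature_strength / background_rate
        Endorsement probability of a cause's own signature symptoms vs. all
        other symptoms; the gap controls cause separability.
    signature_size
        Number of dedicated signature symptoms per cause.
    noise_eps
        Symmetric flip probability applied after the Bernoulli draw, modelling
        respondent misreport.
    missing_rate
        Probability a realised response is replaced by missing (don't know),
        completely at random.
    hce_fraction
        Fraction of symptoms flagged as health-care-experience items.
    site_effect
        Optional per-site additive offset on endorsement probabilities
        (default 0: sites are purely descriptive labels).
    """

    module: str = "adult"
    n_causes: int = 34
    n_symptoms: int = 171
    n_records: int = 7800
    csmf_true: np.ndarray | None = None
    signature_strength: float = 0.8
    background_rate: float = 0.05
    signature_size: int = 3
    noise_eps: float = 0.05
    missing_rate: float = 0.05
    hce_fraction: float = 0.2
    n_sites: int = 6
    site_effect: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.module not in MODULES:
            raise ValueError(f"unknown module {self.module!r}")
        if self.n_causes < 2:
            raise ValueError("need at least 2 causes")
        if not (0.5 < self.signature_strength <= 1.0):
            raise ValueError("signature_strength must be in (0.5, 1]")
        if not (0.0 <= self.background_rate <= 0.5):
            raise ValueError("background_rate must be in [0, 0.5]")
        if not (0.0 <= self.noise_eps <= 0.5):
            raise ValueError("noise_eps must be in [0, 0.5]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if not (0.0 <= self.hce_fraction < 1.0):
            raise ValueError("hce_fraction must be in [0, 1)")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.signature_size * self.n_causes > self.n_symptoms:
            raise ValueError(
                f"signature blocks overlap: {self.signature_size} symptoms x"
                f" {self.n_causes} causes > {self.n_symptoms} symptoms"
            )
        if self.csmf_true is not None:
            csmf = np.asarray(self.csmf_true, dtype=np.float64)
            if csmf.shape != (self.n_causes,):
                raise ValueError("csmf_true length must equal n_causes")
            if (csmf < 0).any() or abs(csmf.sum() - 1.0) > 1e-9:
                raise ValueError("csmf_true must be non-negative and sum to 1 within 1e-9")
            self.csmf_true = csmf

    def resolved_csmf(self) -> np.ndarray:
        if self.csmf_true is not None:
            return self.csmf_true
        return np.full(self.n_causes, 1.0 / self.n_causes)


def _make_symptom_dictionary(config: GeneratorConfig) -> SymptomDictionary:
    # HCE flags are a seeded random subset so that signature and background
    # symptoms are both represented among HCE items (removing them degrades
    # information, as with real health-care-experience questions).
    S = config.n_symptoms
    k = int(round(config.hce_fraction * S))
    k = min(k, S - 1)  # keep at least one non-HCE symptom
    rng = np.random.default_rng(np.random.SeedSequence((int(config.seed), 7)))
    flags = np.zeros(S, dtype=bool)
    if k > 0:
        flags[rng.choice(S, size=k, replace=False)] = True
    width = len(str(S))
    ids = tuple(f"s{j + 1:0{width}d}" for j in range(S))
    return SymptomDictionary(ids, tuple(flags))


def generate_probbase(config: GeneratorConfig) -> Probbase:
    """Build the true signature-block probbase for ``config``.

    Cause ``j`` gets columns ``[j*signature_size, (j+1)*signature_size)`` set
    to ``signature_strength``; every other entry is ``background_rate``.
    Deterministic given the config (the seed only affects HCE flag placement).
    """
    cause_list = default_cause_list(config.module, config.n_causes)
    symptom_dict = _make_symptom_dictionary(config)
    P = np.full((config.n_causes, config.n_symptoms), config.background_rate, dtype=np.float64)
    k = config.signature_size
    for j in range(config.n_causes):
        P[j, j * k:(j + 1) * k] = config.signature_strength
    return Probbase(P, cause_list, symptom_dict, provenance="fixed")


def generate_dataset(probbase_true: Probbase, config: GeneratorConfig) -> VADataset:
    """Draw a synthetic gold-standard dataset from ``probbase_true``.

    Per record: the gold cause is drawn from ``csmf_true``; each symptom is
    Bernoulli(P[cause, s]) (plus the optional per-site offset); the realised
    value is flipped with probability ``noise_eps``; finally it is set to
    missing with probability ``missing_rate``.  Deterministic given the seed.
    """
    if probbase_true.shape != (config.n_causes, config.n_symptoms):
        raise ValueError(
            f"probbase shape {probbase_true.shape} does not match config"
            f" ({config.n_causes}, {config.n_symptoms})"
        )
    n, S = config.n_records, config.n_symptoms
    rng = np.random.default_rng(np.random.SeedSequence((int(config.seed), 1)))
    csmf = config.resolved_csmf()
    cause_idx = rng.choice(config.n_causes, size=n, p=csmf)
    sites = rng.integers(config.n_sites, size=n)

    P = probbase_true.values[cause_idx]  # (n, S)
    if config.site_effect != 0.0 and config.n_sites > 1:
        offsets = config.site_effect * np.linspace(-1.0, 1.0, config.n_sites)
        P = np.clip(P + offsets[sites][:, None], 0.0, 1.0)
    X = (rng.random((n, S)) < P).astype(np.int8)
    if config.noise_eps > 0.0:
        flip = rng.random((n, S)) < config.noise_eps
        X[flip] = 1 - X[flip]
    if config.missing_rate > 0.0:
        X[rng.random((n, S)) < config.missing_rate] = MISSING

    width = len(str(n))
    record_ids = np.array([f"r{i + 1:0{width}d}" for i in range(n)], dtype=object)
    site_labels = np.array([f"site_{s + 1}" for s in sites], dtype=object)
    gold = np.array([probbase_true.cause_list.causes[j] for j in cause_idx], dtype=object)
    return VADataset(
        record_ids=record_ids,
        module=config.module,
        sites=site_labels,
        gold_causes=gold,
        symptoms=X,
        cause_list=probbase_true.cause_list,
        symptom_dict=probbase_true.symptom_dict,
    )


#: (n_causes, n_symptoms, n_records) by module: 34/21/6 causes; 171/86/110
#: symptoms as in a Tariff-2.0-style mapping; record counts near the
#: gold-standard database (7841 adults, 2064 children, 1620 neonates + 1005
#: stillbirths) rounded to 7800 / 2100 / 2600.
_PRESETS = {
    "adult": (34, 171, 7800),
    "child": (21, 86, 2100),
    "neonate": (6, 110, 2600),
}


def phmrc_like_preset(module: str, **overrides) -> GeneratorConfig:
    """Generator config emulating the gold-standard database's structure."""
    if module not in _PRESETS:
        raise ValueError(f"unknown module {module!r}; expected one of {sorted(_PRESETS)}")
    n_causes, n_symptoms, n_records = _PRESETS[module]
    cfg = GeneratorConfig(module=module, n_causes=n_causes, n_symptoms=n_symptoms,
                          n_records=n_records)
    return replace(cfg, **overrides) if overrides else cfg
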