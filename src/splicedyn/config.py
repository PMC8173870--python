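"""Pipeline-wide thresholds with their defaults.

Every threshold used by the callers lives here so that analyses can be
re-run with one YAML file. The defaults are the values the pipeline was
designed around: |ΔPSI| ≥ 10 with a replicate range of 5 for a
differential-splicing call, 10 reads for a trustworthy PSI estimate,
|ΔΔPSI| ≥ 10 / < 2 for perturbation dependence / independence, and a
fuzzy-membership cutoff of 0.3 for regulator calls.
"""

from __future__ import annotations

from typing import Any

import yaml

DEFAULTS: dict[str, Any] = {
    # PSI quantification / differential splicing
    "min_reads": 10,        # below this, a PSI cell is flagged VLOW
    "dpsi_min": 10.0,       # |mean PSI difference| for a diff call
    "range_min": 5.0,       # minimal cross-condition replicate gap
    "sign_consistent_range": True,
    # perturbation dependency
    "ddpsi_min": 10.0,
    "ddpsi_indep_max": 2.0,
    "base_change_min": 10.0,
    # APA
    "tpm_min": 3.0,
    "apa_min_samples": 10,
    "apa_min_sites": 2,
    "ddpau_min": 10.0,
    # expression filters
    "cpm_min": 5.0,
    "frac_samples": 1.0 / 3.0,
    "cv_min": 0.2,
    # clustering / regulator inference
    "fuzzifier": 1.25,
    "membership_min": 0.3,
    # RNA maps
    "map_window": 31,
    "map_n_perm": 1000,
    "map_alpha": 0.05,
    # ORF impact
    "truncation_aa": 300,
    "nmd_rule_nt": 50,
}


def load_config(path: str | None = None) -> dict[str, Any]:
    """Return the default config, optionally updated from a YAML file.

    Unknown keys in the file are kept (callers may carry extra
    settings); known keys override the defaults.
    """
    cfg = dict(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config file {path!r} must contain a mapping")
        cfg.update(user)
    return cfg
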