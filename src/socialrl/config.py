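"""Run configuration: YAML-backed, with documented defaults.

The configuration has four sections — ``cohort`` (who is simulated),
``task`` (trial schedule), ``fitting`` (estimation settings), and
``inference`` (mixed-model stage). Unknown keys are an error rather than
being silently ignored, so a typo cannot quietly fall back to a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["TaskConfig", "CohortConfig", "FittingConfig", "InferenceConfig",
           "RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Malformed configuration: unknown, duplicated, or mistyped keys."""


@dataclass
class TaskConfig:
    """Trial schedule for the selection task.

    The original task's exact trial counts live in an unavailable supplement;
    these defaults (20 presentations per training pair per block, 4 blocks,
    and every recombined pair 4 times in the test phase) match the scale the
    paradigm is normally run at and give the fitter enough trials to recover
    learning rates.
    """

    trials_per_pair_per_block: int = 20
    n_blocks: int = 4
    test_repetitions: int = 4

    @property
    def n_training_trials(self) -> int:
        return self.trials_per_pair_per_block * self.n_blocks * 3

    @property
    def n_test_trials(self) -> int:
        return self.test_repetitions * 15  # 15 unordered pairs of 6 faces


@dataclass
class CohortConfig:
    """Ground-truth population the synthetic cohort is drawn from.

    Learning rates are drawn logit-normal around 0.23 (the scale of the
    session-1 group means), inverse temperatures log-normal around 5.
    ``cbmi_session2_alpha_shift`` is the session-2 shift applied to both
    learning rates of CBM-I subjects on the raw probability scale; 0 is the
    null world, and the non-null scenario used for power checks is -0.02 per
    half-level of the effects-coded factors (the magnitude of the printed
    session-by-condition coefficient).
    """

    n_cbmi: int = 51
    n_ema: int = 55
    alpha_logit_mean: float = -1.2  # logistic(-1.2) ~ 0.23
    alpha_logit_sd: float = 0.5
    beta_log_mean: float = 1.6  # exp(1.6) ~ 5
    beta_log_sd: float = 0.3
    cbmi_session2_alpha_shift: float = 0.0
    session2_pe_valence_shift: float = 0.0
    speech_weight_mean: float = 0.5
    speech_weight_sd: float = 0.15
    speech_noise_sd: float = 6.0
    speech_pe_valence_effect: float = 0.0
    speech_item_valence_effect: float = 0.0
    pre_rating_low: int = 20
    pre_rating_high: int = 80


@dataclass
class FittingConfig:
    n_restarts: int = 4
    beta_max: float = 20.0
    hierarchical: bool = False
    n_warmup: int = 600
    n_draws: int = 400
    n_chains: int = 2


@dataclass
class InferenceConfig:
    outlier_threshold: str = "4/n"
    emm_scale: str = "response"  # or "logit" for post hoc contrasts
    alpha_level: float = 0.05


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    task: TaskConfig = field(default_factory=TaskConfig)
    fitting: FittingConfig = field(default_factory=FittingConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    seed: int = 0


_SECTIONS = {
    "cohort": CohortConfig,
    "task": TaskConfig,
    "fitting": FittingConfig,
    "inference": InferenceConfig,
}


class _DuplicateKeySafeLoader(yaml.SafeLoader):
    pass


def _no_duplicates(loader, node, deep=False):
    seen = set()
    for key_node, _ in node.value:
        key = loader.construct_object(key_node, deep=deep)
        if key in seen:
            raise ConfigError(f"duplicate (conflicting) config key: {key!r}")
        seen.add(key)
    return loader.construct_mapping(node, deep=deep)


_DuplicateKeySafeLoader.add_constructor(
    yaml.resolver.BaseResolver.DEFAULT_MAPPING_TAG, _no_duplicates
)


def _build_section(cls, data: dict, section: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(
            f"unknown key(s) in section {section!r}: {', '.join(sorted(unknown))}"
        )
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        try:
            if ftype == "int":
                value = int(value)
            elif ftype == "float":
                value = float(value)
            elif ftype == "bool":
                if not isinstance(value, bool):
                    raise ValueError("expected a boolean")
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"bad value for {section}.{name}: {exc}") from None
        kwargs[name] = value
    return cls(**kwargs)


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML config, applying defaults for anything unspecified.

    An empty (or absent) file yields all defaults. ``overrides`` is a nested
    dict merged on top of the file, used by the CLI for flag overrides.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.load(text, Loader=_DuplicateKeySafeLoader)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config root must be a mapping")
        data = loaded
    for section, content in (overrides or {}).items():
        if isinstance(content, dict):
            data.setdefault(section, {}).update(content)
        else:
            data[section] = content

    unknown = set(data) - set(_SECTIONS) - {"seed"}
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {', '.join(sorted(unknown))}")

    kwargs = {}
    for section, cls in _SECTIONS.items():
        section_data = data.get(section, {})
        if not isinstance(section_data, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        kwargs[section] = _build_section(cls, section_data, section)
    seed = data.get("seed", 0)
    if not isinstance(seed, int):
        raise ConfigError("seed must be an integer")
    return RunConfig(seed=seed, **kwargs)
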