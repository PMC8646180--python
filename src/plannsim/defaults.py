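"""Packaged default configuration.

The default generative model (covariate strata, log-normal AFT coefficients,
Weibull censoring specifications) and the frozen tuned hyperparameters live in
a versioned YAML file shipped with the package
(``plannsim/data/default_config.yaml``). Users can point any entry point at
their own config file with the same schema.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

DEFAULT_CONFIG_RESOURCE = "default_config.yaml"


@lru_cache(maxsize=None)
def _default_config_text() -> str:
    return (
        resources.files("plannsim.data").joinpath(DEFAULT_CONFIG_RESOURCE).read_text()
    )


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Load a study configuration; the packaged default when ``path`` is None."""
    if path is None:
        return yaml.safe_load(_default_config_text())
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(config: dict[str, Any], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
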