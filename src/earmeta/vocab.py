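"""Pathway-keyword vocabulary used to screen candidate-gene annotations.

The vocabulary maps a pathway key (e.g. ``auxin``, ``CLV-WUS``, ``WD40``) to
annotation keywords.  Matching is deliberately plain: case-insensitive
substring search over a gene's free-text annotation, so every assignment is
auditable.  The packaged default distils the molecular modules known to
regulate maize female-inflorescence development; it is a curatorial starting
point and fully user-overridable via YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .core import ConfigError

__all__ = ["PathwayVocabulary", "default_vocabulary"]


@dataclass(frozen=True)
class PathwayVocabulary:
    """Mapping of pathway key -> tuple of annotation keywords."""

    pathways: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if not self.pathways:
            raise ConfigError("empty pathway vocabulary")
        for key, kws in self.pathways.items():
            if not kws:
                raise ConfigError(f"pathway {key!r} has no keywords")

    @classmethod
    def from_dict(cls, d: Mapping[str, Sequence[str]]) -> "PathwayVocabulary":
        return cls({str(k): tuple(str(w) for w in v) for k, v in d.items()})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PathwayVocabulary":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ConfigError(f"{path}: vocabulary YAML must map pathway -> keywords")
        return cls.from_dict(d)

    def match(self, text: str) -> dict[str, list[str]]:
        """Pathways whose keywords occur in ``text`` (case-insensitive substring).

        Returns ``{pathway: [keywords hit]}`` for pathways with ≥1 hit.
        """
        low = text.lower()
        hits: dict[str, list[str]] = {}
        for key, kws in self.pathways.items():
            found = [w for w in kws if w.lower() in low]
            if found:
                hits[key] = found
        return hits

    def without_keyword(self, keyword: str) -> "PathwayVocabulary":
        """Copy with one keyword removed everywhere (empty pathways dropped)."""
        pruned = {
            k: tuple(w for w in v if w != keyword) for k, v in self.pathways.items()
        }
        return PathwayVocabulary({k: v for k, v in pruned.items() if v})


def default_vocabulary() -> PathwayVocabulary:
    """The packaged default vocabulary."""
    ref = resources.files("earmeta").joinpath("data/pathway_vocabulary.yaml")
    d = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return PathwayVocabulary.from_dict(d)
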