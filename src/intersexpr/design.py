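"""Sample-sheet container for the backcross RNA-seq design.

The study design crosses three factors: species (U = *Ae. aegypti* Uganda,
M = *Ae. mascarensis*, UUM = backcross generation), sex (male, female, and —
for the backcross only — intersex), and tissue (reproductive organs vs.
carcass).  The full design has 14 (species, sex, tissue) groups with three
biological replicates each, 42 samples in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

SPECIES = ("U", "M", "UUM")
SEXES = ("male", "female", "intersex")
TISSUES = ("reproductive", "carcass")

#: Species whose samples come from pure (non-hybrid) colonies.
PURE_SPECIES = ("U", "M")


def group_key(species: str, sex: str, tissue: str) -> str:
    """Canonical label for one (species, sex, tissue) group, e.g. ``U_female_reproductive``."""
    return f"{species}_{sex}_{tissue}"


class DesignError(ValueError):
    """Raised when a sample sheet violates a design invariant."""


@dataclass(frozen=True)
class Sample:
    sample_id: str
    species: str
    sex: str
    tissue: str
    replicate: int

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise DesignError(
                f"sample {self.sample_id!r}: unknown species {self.species!r} "
                f"(expected one of {SPECIES})"
            )
        if self.sex not in SEXES:
            raise DesignError(
                f"sample {self.sample_id!r}: unknown sex {self.sex!r} (expected one of {SEXES})"
            )
        if self.tissue not in TISSUES:
            raise DesignError(
                f"sample {self.sample_id!r}: unknown tissue {self.tissue!r} "
                f"(expected one of {TISSUES})"
            )
        if self.sex == "intersex" and self.species != "UUM":
            raise DesignError(
                f"sample {self.sample_id!r}: intersex individuals only occur in the "
                f"UUM backcross, not species {self.species!r}"
            )
        if self.replicate < 1:
            raise DesignError(f"sample {self.sample_id!r}: replicate index must be >= 1")

    @property
    def group(self) -> str:
        return group_key(self.species, self.sex, self.tissue)


@dataclass
class DesignSpec:
    """An ordered collection of samples with unique IDs."""

    samples: list[Sample] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise DesignError(f"duplicate sample IDs: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def groups(self) -> dict[str, list[str]]:
        """Map group label -> ordered sample IDs."""
        out: dict[str, list[str]] = {}
        for s in self.samples:
            out.setdefault(s.group, []).append(s.sample_id)
        return out

    def group_samples(self, group: str) -> list[str]:
        got = self.groups().get(group)
        if not got:
            raise DesignError(f"group {group!r} has no samples in this design")
        return got

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "species": [s.species for s in self.samples],
                "sex": [s.sex for s in self.samples],
                "tissue": [s.tissue for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
            }
        )


def default_design(n_replicates: int = 3) -> DesignSpec:
    """The study's 14-group design: 2 pure species x sex x tissue, plus the
    backcross with males, females and intersexes in both tissues."""
    samples = []
    combos: list[tuple[str, str]] = []
    for species in ("U", "M"):
        for sex in ("male", "female"):
            combos.append((species, sex))
    for sex in ("male", "female", "intersex"):
        combos.append(("UUM", sex))
    for species, sex in combos:
        for tissue in TISSUES:
            for rep in range(1, n_replicates + 1):
                sid = f"{species}_{sex}_{tissue}_r{rep}"
                samples.append(Sample(sid, species, sex, tissue, rep))
    return DesignSpec(samples)
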