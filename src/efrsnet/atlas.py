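"""90-region cortical/subcortical atlas labels and pair ordering.

The atlas is the classic 90-region automated anatomical labelling scheme
(45 bilateral structures, left/right interleaved), identified by the usual
abbreviations, e.g. ``MOG.L`` for the left middle occipital gyrus and
``PAL.L`` for the left pallidum. All connectivity matrices in this package
are labelled with, and ordered by, this list; vectorized connectivity uses
the upper triangle in row-major order, pair (i, j) with i < j.
"""

from __future__ import annotations

from importlib import resources
from functools import lru_cache

__all__ = ["load_atlas_labels", "label_index", "upper_triangle_pairs"]


@lru_cache(maxsize=1)
def load_atlas_labels() -> tuple[str, ...]:
    """Return the 90 atlas region abbreviations in canonical order."""
    text = (
        resources.files("efrsnet").joinpath("data/aal90_labels.txt").read_text()
    )
    labels = tuple(line.strip() for line in text.splitlines() if line.strip())
    if len(labels) != 90:
        raise RuntimeError(f"atlas file corrupt: {len(labels)} labels, expected 90")
    return labels


def label_index(labels: tuple[str, ...] | None = None) -> dict[str, int]:
    """Map region abbreviation -> position in the canonical ordering."""
    if labels is None:
        labels = load_atlas_labels()
    return {lab: i for i, lab in enumerate(labels)}


def upper_triangle_pairs(labels) -> list[tuple[str, str]]:
    """Region pairs (i, j), i < j, in row-major upper-triangle order.

    This is the column ordering contract for every vectorized connectivity
    feature matrix in the package.
    """
    labels = list(labels)
    return [
        (labels[i], labels[j])
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    ]
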