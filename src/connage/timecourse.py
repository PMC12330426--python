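"""Per-subject component time-course container.

A :class:`TimecourseMatrix` holds the post-ICA signals for one resting-state
scan: a frames x components array together with the repetition time (TR, the
seconds between acquired frames) and the component labels. It is the unit of
data every stage of the pipeline consumes and produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class TimecourseMatrix:
    """Component time courses for one scan.

    Parameters
    ----------
    data : ndarray of shape (n_frames, n_components)
        Signal values, one column per independent component.
    tr_seconds : float
        Repetition time in seconds; must be positive.
    subject_id : str
        Identifier linking the scan to its phenotype row.
    component_ids : sequence of str, optional
        Ordered component labels. Defaults to ``IC01 .. ICnn``.
    """

    data: np.ndarray
    tr_seconds: float
    subject_id: str = "subject"
    component_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(
                f"time-course data must be 2-D (frames x components), got shape {self.data.shape}"
            )
        if not self.tr_seconds > 0:
            raise ValueError(f"tr_seconds must be positive, got {self.tr_seconds}")
        if not self.component_ids:
            width = max(2, len(str(self.data.shape[1])))
            self.component_ids = tuple(
                f"IC{i + 1:0{width}d}" for i in range(self.data.shape[1])
            )
        self.component_ids = tuple(self.component_ids)
        if len(self.component_ids) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.component_ids)} component ids for {self.data.shape[1]} columns"
            )

    @property
    def frame_count(self) -> int:
        return self.data.shape[0]

    @property
    def n_components(self) -> int:
        return self.data.shape[1]

    @property
    def duration_seconds(self) -> float:
        """Scan duration = frames x TR."""
        return self.frame_count * self.tr_seconds

    def with_data(self, data: np.ndarray) -> "TimecourseMatrix":
        """Copy of this scan with replaced signal values (metadata kept)."""
        return replace(self, data=np.asarray(data, dtype=float))
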