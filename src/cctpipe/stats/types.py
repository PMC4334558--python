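"""Result containers shared by the statistical routines."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field


@dataclass(frozen=True)
class TestResult:
    """A named statistic with its degrees of freedom, p-value and context.

    ``decision_path`` records which branch of the normality/homoscedasticity
    logic produced the test (empty for stand-alone calls).
    """

    name: str
    statistic: float
    p_value: float
    df: float | tuple[float, float] | None = None
    ci95: tuple[float, float] | None = None
    estimate: float | None = None
    decision_path: str = ""
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci95: tuple[float, float]
    model_tag: str = "ICC(A,1) two-way mixed absolute agreement"
    n_subjects: int = 0
    n_raters: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if lo > self.icc + 1e-9 or hi < self.icc - 1e-9:
            raise ValueError("confidence interval does not bracket the estimate")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    sd: float
    n: int
    median: float
    iqr: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.sd < 0 or self.iqr < 0:
            raise ValueError("sd and iqr must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)
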