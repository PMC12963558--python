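"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's computational paths: the ANOVA oracle
works by general-linear-model projection (design matrices and residual sums
of squares via least squares), and the band-power oracle computes Hann
periodograms directly from the FFT definition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _sse(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def mixed_anova_oracle(data: pd.DataFrame, dv: str = "value",
                       within: str = "condition", between: str = "group",
                       subject: str = "subject_id") -> dict:
    """Type III sums of squares for the 2x2 mixed design via model
    comparison on effect-coded design matrices.

    Within-stratum terms drop columns from the full model (intercept, group,
    condition, interaction, sum-to-zero subject deviations nested in group);
    the between-stratum term comes from the one-way projection on subject
    means, scaled by the two repeated measures.
    """
    df = data.copy()
    conds = sorted(df[within].unique())
    groups = sorted(df[between].unique())
    subjects = sorted(df[subject].unique())
    df["_c"] = np.where(df[within] == conds[0], 1.0, -1.0)
    df["_g"] = np.where(df[between] == groups[0], 1.0, -1.0)
    y = df[dv].to_numpy(float)

    # sum-to-zero subject deviation columns, nested within group
    sub_cols = []
    grp_of = df.drop_duplicates(subject).set_index(subject)[between]
    for g in groups:
        members = [s for s in subjects if grp_of[s] == g]
        for s in members[:-1]:
            col = np.where(df[subject] == s, 1.0,
                           np.where(df[subject] == members[-1], -1.0, 0.0))
            sub_cols.append(col)
    S = np.column_stack(sub_cols)
    one = np.ones(len(df))
    C = df["_c"].to_numpy()
    G = df["_g"].to_numpy()
    GC = G * C

    X_full = np.column_stack([one, G, C, GC, S])
    sse_full = _sse(y, X_full)
    ss_cond = _sse(y, np.column_stack([one, G, GC, S])) - sse_full
    ss_inter = _sse(y, np.column_stack([one, G, C, S])) - sse_full
    ss_wresid = sse_full

    means = df.groupby(subject)[dv].mean()
    gm = grp_of.loc[means.index]
    ym = means.to_numpy(float)
    Gm = np.where(gm == groups[0], 1.0, -1.0)
    onem = np.ones(len(ym))
    sse_b_full = _sse(ym, np.column_stack([onem, Gm]))
    ss_group = 2.0 * (_sse(ym, onem[:, None]) - sse_b_full)
    ss_bresid = 2.0 * sse_b_full

    n = len(subjects)
    return {
        "condition": ss_cond, "interaction": ss_inter,
        "within_resid": ss_wresid, "group": ss_group,
        "between_resid": ss_bresid,
        "df": {"condition": 1, "interaction": 1, "within_resid": n - 2,
               "group": 1, "between_resid": n - 2},
    }


def band_power_oracle(epoch: np.ndarray, fs: float,
                      band: tuple[float, float],
                      subset_idx: list[int]) -> float:
    """Band power of one epoch from the FFT definition: Hann-windowed
    one-sided periodogram density per channel, rectangle-integrated over
    [low, high), then averaged over the subset."""
    low, high = band
    powers = []
    for ch in subset_idx:
        x = np.asarray(epoch[ch], dtype=float)
        n = x.size
        # periodic Hann window, written out from its cosine definition
        w = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(n) / n)
        spec = np.fft.rfft(x * w)
        psd = (np.abs(spec) ** 2) / (fs * (w @ w))
        psd[1:] *= 2.0
        if n % 2 == 0:
            psd[-1] /= 2.0
        freqs = np.fft.rfftfreq(n, 1.0 / fs)
        df = freqs[1] - freqs[0]
        sel = (freqs >= low) & (freqs < high)
        powers.append(psd[sel].sum() * df)
    return float(np.mean(powers))


def random_mixed_dataset(rng: np.random.Generator, n1: int, n2: int
                         ) -> pd.DataFrame:
    """A random complete 2x2 mixed dataset with group sizes n1 and n2."""
    rows = []
    for g, n in (("g1", n1), ("g2", n2)):
        for i in range(n):
            sid = f"{g}_s{i}"
            base = rng.normal(scale=2.0)
            for cond in ("A", "B"):
                rows.append((sid, g, cond, base + rng.normal()))
    return pd.DataFrame(rows, columns=["subject_id", "group", "condition",
                                       "value"])
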