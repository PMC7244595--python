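"""Result persistence: HDF5 for raw estimator sets, TSV for tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .hf import QMCResult

__all__ = ["save_result", "load_result", "result_to_tsv"]

_SCALARS = ("beta", "dtau", "L", "n_orb", "n_host", "m2_total", "m2_total_err",
            "chi_t", "chi_t_err", "total_N", "total_N_err", "sign", "sign_err",
            "acceptance_rate")
_ARRAYS = ("occ", "occ_err", "pair_density", "pair_density_err",
           "site_moment_corr", "site_moment_corr_err")


def save_result(path, result: QMCResult) -> None:
    """Write a QMCResult to an HDF5 container."""
    import h5py
    with h5py.File(path, "w") as fh:
        for k in _SCALARS:
            fh.attrs[k] = getattr(result, k)
        for k in _ARRAYS:
            fh.create_dataset(k, data=getattr(result, k))
        if result.tau_corr is not None:
            fh.create_dataset("tau_corr", data=result.tau_corr)
            fh.create_dataset("tau_corr_err", data=result.tau_corr_err)
            fh.attrs["chi_t_tau"] = result.chi_t_tau
            fh.attrs["chi_t_tau_err"] = result.chi_t_tau_err
        meta = fh.create_group("meta")
        for k, v in result.meta.items():
            if k == "warnings":
                meta.attrs[k] = "\n".join(v)
            elif v is not None and not isinstance(v, dict):
                meta.attrs[k] = v


def load_result(path) -> QMCResult:
    import h5py
    with h5py.File(path, "r") as fh:
        kwargs = {k: fh.attrs[k] for k in _SCALARS}
        kwargs["L"] = int(kwargs["L"])
        kwargs["n_orb"] = int(kwargs["n_orb"])
        kwargs["n_host"] = int(kwargs["n_host"])
        for k in _ARRAYS:
            kwargs[k] = np.asarray(fh[k])
        meta = {k: fh["meta"].attrs[k] for k in fh["meta"].attrs}
        if "warnings" in meta:
            meta["warnings"] = [w for w in str(meta["warnings"]).split("\n") if w]
        r = QMCResult(meta=meta, **kwargs)
        if "tau_corr" in fh:
            r.tau_corr = np.asarray(fh["tau_corr"])
            r.tau_corr_err = np.asarray(fh["tau_corr_err"])
            r.chi_t_tau = float(fh.attrs["chi_t_tau"])
            r.chi_t_tau_err = float(fh.attrs["chi_t_tau_err"])
    return r


def result_to_tsv(path, result: QMCResult) -> None:
    """One row per scalar observable: name, value, error, bin count."""
    df = result.to_frame()
    df["n_bins"] = result.meta.get("n_bins", "")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
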