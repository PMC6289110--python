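"""Derive forcings and assemble the merged model-input table.

Reads the raw series written by 01_simulate_site.py, derives oxygen
saturation, depth, velocity and merged PPFD, interpolates everything onto
the O2 timestamps, applies the gap (>3 h), positive-flow and complete-window
rules, and writes the per-chunk input tables plus daily predictor aggregates
under results/prepared/.
"""

import os

from rivermetab import io as rio
from rivermetab.cli import RAW_VARIABLES
from rivermetab.forcings import daily_forcing_summaries, derive_forcings
from rivermetab.input_prep import prepare_model_input

SITE_DIR = os.path.join("results", "site")
OUT = os.path.join("results", "prepared")
SITE_ID = "synth00"


def main():
    os.makedirs(OUT, exist_ok=True)
    raws = {var: rio.read_timeseries(rio.timeseries_path(SITE_DIR, SITE_ID, var))
            for var in RAW_VARIABLES}
    site = rio.read_site_record(os.path.join(SITE_DIR, f"{SITE_ID}_site.yml"))
    inputs = prepare_model_input(site, raws)
    for i, mi in enumerate(inputs):
        rio.write_model_input(mi, os.path.join(OUT, f"{SITE_ID}_input_{i}.tsv"))
        excluded = [v for v in mi.validity if not v.valid]
        print(f"chunk {i}: {mi.resolution_min:g}-min resolution, "
              f"{len(mi.valid_dates)} valid / {len(mi.validity)} candidate days"
              + (f", excluded: {[(str(v.date), v.reason) for v in excluded]}"
                 if excluded else ""))
    derived = derive_forcings(site, raws)
    predictors = daily_forcing_summaries(site, raws, derived)
    predictors.to_csv(os.path.join(OUT, f"{SITE_ID}_daily_predictors.tsv"),
                      sep="\t")
    print(f"wrote inputs and daily predictors to {OUT}/")


if __name__ == "__main__":
    main()
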