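# RAM Legacy export

The empirical reproduction reads two CSVs from this directory, neither of
which is distributed with the package:

- `timeseries.csv` — columns `stock_id, series_id, year, value`
- `refpoints.csv` — columns `stock_id, parameter_id, value`

Recipe (one-time, needs R and a network connection):

1. Download the pinned archive from Zenodo, DOI 10.5281/zenodo.3676088
   (RAM Legacy Stock Assessment Database v4.44).
2. In R, load the bundled `.RData` and export the `timeseries` table
   (columns stockid/tsid/tsyear/tsvalue) and the `bioparams` table
   (stockid/bioid/biovalue) with `write.csv`, renaming the columns to the
   names above. The default series aliases in `fishstatus.ramio` already
   understand the RAM tsid stems (TBbest, SSBbest, BdivBmsypref, ERbest,
   UdivUmsypref, TCbest, TBmsybest, ERmsybest).
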