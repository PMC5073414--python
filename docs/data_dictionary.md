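# Data dictionary

All files are UTF-8, comma-delimited CSV with a header row.  Missing values
are empty strings.  Dates are ISO 8601 (`YYYY-MM-DD`).

## registry.csv — population registry

| column | meaning |
| --- | --- |
| `key` | unique registry person key (`R` + 7 digits) |
| `surname` | surname as recorded |
| `given_names` | given name(s), space-separated |
| `sex` | `F` or `M` |
| `birth_date` | date of birth |
| `coverage_start` | earliest date of coverage eligibility |
| `last_contact` | last date of contact with the covered system |
| `postal_code` | residential postal code (6-character, no space) |

## source.csv — extract to be linked

| column | meaning |
| --- | --- |
| `source_id` | unique source record id (`S` + 7 digits) |
| `surname`, `given_names`, `sex`, `birth_date`, `postal_code` | identifiers as recorded (possibly corrupted/missing) |
| `event_date` | landing date (immigration) or death date (death) |
| `event_year` | year of `event_date` (convenience column) |
| `immigrant_class`, `region_of_birth` | stratification attributes (immigration kind) |
| `cause_of_death` | stratification attribute (death kind) |

## truth.csv — ground-truth map (synthetic studies only)

| column | meaning |
| --- | --- |
| `source_id` | source record id |
| `registry_key` | true registry key, or empty for structurally unlinkable records |

## postal table (e.g. `postal_city_toy.csv`)

| column | meaning |
| --- | --- |
| `prefix` | postal-code prefix (longest prefix wins at lookup) |
| `city` | city/region code |

## Run artifacts (written by `reglink link`)

| file | contents |
| --- | --- |
| `link_table.csv` | `source_id, link_key, status, pass_id, weight, dedup` — one row per source record; `link_key` empty when unlinked; `dedup` ∈ {survivor, discarded, empty} |
| `review_audit.csv` | every grey-zone pair: weight, competitor gap, city codes from both files, per-field comparison outcomes |
| `dedup_audit.csv` | discarded duplicates with the surviving record and the retention reason |
| `strata_<variable>.tsv` | per-stratum linked/unlinked counts, within-file %, standardized difference, linkage rate |
| `era_series.tsv` | per event-year band: linkage rate and deterministic/probabilistic/unlinked percentages |
| `summary.json` | overall rate, method mix, per-pass counts, review and dedup tallies, truth metrics when a truth file was given |
| `run.log` | per-pass counts and settings sufficient to redraw the linkage flow diagram |
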