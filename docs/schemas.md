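# File schemas

All stages exchange plain delimited text. Column names equal the domain-type
field names; units are fixed at ingest (see `dietswap.core`).

## persons.csv

One row per respondent.

| column | type | notes |
|---|---|---|
| person_id | str | opaque identifier |
| age_years | float | completed years used for banding |
| gender | str | `male` / `female` |
| race | str | `hispanic`, `nh_white`, `nh_black`, `other` |
| income_band | str | `lt20k`, `20to75k`, `75to100k`, `gt100k` |
| education_band | str | `lt9`, `9to11`, `hs`, `some_college`, `college` |
| nut_status | str | `walnut` / `other_nut` / `no_nut`, empty if unclassified |
| breast_milk | bool | child consuming breast milk |
| pregnant_or_lactating | bool | |
| reliable_recall | bool | recall flagged complete and reliable |
| animal_protein_missing | bool | missing animal-protein food-pattern fields |
| day1_weekday | bool | day-1 recall fell Mon-Thu |
| day2_weekday | bool or empty | empty when day 2 was not completed |

## food_records.csv

One row per food item per person-day. A missing day 2 is the absence of
rows, never zeros.

| column | type | notes |
|---|---|---|
| person_id | str | must exist in persons.csv |
| day | int | 1 or 2 |
| food_code | str | opaque code |
| walnut_flag | bool | item contains walnuts |
| grams | float | consumed amount |
| wweia_category | str | food-category label used for price imputation |
| energy ... vitamin_b12 | float | the 19 nutrient fields (kcal, g, mg, µg) |
| meat_oz ... added_sugars_tsp | float | the 19 food-pattern fields (oz/cup/tsp eq) |

Person-day aggregates are recomputed at read time as the component-wise sum
of that person-day's rows.

## weights.csv

| column | type | notes |
|---|---|---|
| person_id | str | |
| base_weight | float | > 0 |
| rep_0 ... rep_{R-1} | float | Fay-adjusted BRR replicate weights |

## dri.csv

| column | type | notes |
|---|---|---|
| nutrient | str | field name from the nutrient vector |
| gender | str | `male`, `female` or `any` |
| age_min, age_max | int | inclusive band in completed years |
| kind | str | `EAR`, `AI` or `limit` |
| value | float | > 0, in the nutrient's fixed unit |

## prices.csv

| column | type | notes |
|---|---|---|
| food_code | str | |
| category | str | price/CPI category |
| price_per_100g | float | base-year USD per 100 g |
| imputed | bool | price borrowed from the category median |

## cpi.csv

| column | type | notes |
|---|---|---|
| category | str | matches prices.csv categories |
| year | int | |
| index | float | > 0 |
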