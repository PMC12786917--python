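{
 "predicate": {"source": "SP_COUNT", "comparator": "GT", "threshold": 8.5},
 "no": "NO_EMS",
 "yes": {
  "predicate": {"source": "SUM_VAS", "comparator": "GT", "threshold": 12},
  "no": "NO_EMS",
  "yes": {
   "predicate": {"source": "ITEM", "comparator": "GT", "item_id": "strongest_4wks_nrs", "threshold": 3},
   "no": "NO_EMS",
   "yes": {
    "predicate": {"source": "ITEM", "comparator": "IS_TRUE", "item_id": "dysuria"},
    "yes": "EMS",
    "no": {
     "predicate": {"source": "ITEM", "comparator": "IS_TRUE", "item_id": "dyspareunia"},
     "yes": "EMS",
     "no": {
      "predicate": {"source": "ITEM", "comparator": "IS_TRUE", "item_id": "obstipation"},
      "yes": "EMS",
      "no": {
       "predicate": {"source": "ITEM", "comparator": "IS_TRUE", "item_id": "loc_thighs_legs"},
       "yes": "EMS",
       "no": {
        "predicate": {"source": "ITEM", "comparator": "IS_TRUE", "item_id": "loc_vagina_mons"},
        "yes": "EMS",
        "no": {
         "predicate": {"source": "ITEM", "comparator": "IS_TRUE", "item_id": "adj_cramping"},
         "yes": "EMS",
         "no": {
          "predicate": {"source": "ITEM", "comparator": "IS_TRUE", "item_id": "adj_pulling"},
          "yes": "EMS",
          "no": {
           "predicate": {"source": "ITEM", "comparator": "IS_TRUE", "item_id": "adj_flashing"},
           "yes": "EMS",
           "no": "NO_EMS"
          }
         }
        }
       }
      }
     }
    }
   }
  }
 }
}
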