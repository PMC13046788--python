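{
 "graphs": [
  {
   "nodes": [
    {"id": "MONDO:0099020", "lbl": "skeletal dysplasia with short stature (toy grouping)", "type": "CLASS", "meta": {"synonyms": []}},
    {"id": "MONDO:0000127", "lbl": "geleophysic dysplasia", "type": "CLASS", "meta": {"synonyms": [{"pred": "hasExactSynonym", "val": "geleophysic dwarfism"}]}},
    {"id": "MONDO:0099001", "lbl": "geleophysic dysplasia 1", "type": "CLASS", "meta": {"synonyms": [{"pred": "hasExactSynonym", "val": "geleophysic dysplasia type 1"}]}},
    {"id": "MONDO:0013612", "lbl": "geleophysic dysplasia 2", "type": "CLASS", "meta": {"synonyms": [{"pred": "hasExactSynonym", "val": "geleophysic dysplasia type 2"}]}},
    {"id": "MONDO:0099003", "lbl": "geleophysic dysplasia 3", "type": "CLASS", "meta": {"synonyms": [{"pred": "hasExactSynonym", "val": "geleophysic dysplasia type 3"}]}},
    {"id": "MONDO:0099010", "lbl": "acromicric dysplasia", "type": "CLASS", "meta": {"synonyms": []}},
    {"id": "MONDO:0099011", "lbl": "Marfan syndrome", "type": "CLASS", "meta": {"synonyms": [{"pred": "hasExactSynonym", "val": "Marfan's syndrome"}]}},
    {"id": "MONDO:0099012", "lbl": "Loeys-Dietz syndrome", "type": "CLASS", "meta": {"synonyms": []}},
    {"id": "MONDO:0099013", "lbl": "Bardet-Biedl syndrome", "type": "CLASS", "meta": {"synonyms": [{"pred": "hasExactSynonym", "val": "BBS"}]}},
    {"id": "MONDO:0099099", "lbl": "obsolete geleophysic syndrome", "type": "CLASS", "meta": {"deprecated": true, "synonyms": []}}
   ],
   "edges": [
    {"sub": "MONDO:0000127", "pred": "is_a", "obj": "MONDO:0099020"},
    {"sub": "MONDO:0099010", "pred": "is_a", "obj": "MONDO:0099020"},
    {"sub": "MONDO:0099001", "pred": "is_a", "obj": "MONDO:0000127"},
    {"sub": "MONDO:0013612", "pred": "is_a", "obj": "MONDO:0000127"},
    {"sub": "MONDO:0099003", "pred": "is_a", "obj": "MONDO:0000127"}
   ]
  }
 ]
}
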