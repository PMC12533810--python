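# New York validation-region groupings used as aggregation labels when
# comparing modeled county burdens with regional ED-visit series.
NYC:
  - Bronx
  - Brooklyn
  - Manhattan
  - Queens
  - Staten Island
Upper Hudson:
  - Albany
  - Columbia
  - Fulton
  - Greene
  - Montgomery
  - Rensselaer
  - Saratoga
  - Schenectady
  - Schoharie
  - Washington
Eastern Lake Ontario:
  - Jefferson
  - Monroe
  - Oswego
  - Wayne
Central:
  - Allegany
  - Broome
  - Cayuga
  - Chemung
  - Chenango
  - Cortland
  - Delaware
  - Herkimer
  - Livingston
  - Madison
  - Oneida
  - Onondaga
  - Ontario
  - Otsego
  - Schuyler
  - Seneca
  - Steuben
  - Tioga
  - Tompkins
  - Yates
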