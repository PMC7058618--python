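district_id,year,icd10,count
DA,2010,E10.8,3
DA,2010,E10.9,5
DA,2010,I20.9,2
DA,2010,I24.0,1
DA,2010,I24.1,4
DA,2010,J450,2
DA,2010,C50.9,7
DA,2010,R02,1
DA,2010,K25.2,2
DA,2010,K25.3,9
DA,2010,N39.0,1
DA,2010,I13.0,2
DA,2010,I13.1,3
DA,2010,Z00,4
DA,2011,J44.9,4
DA,2011,J46,1
DA,2011,N30.0,2
DA,2011,N30.1,6
DA,2011,H66.0,3
DA,2011,L08.1,2
DA,2011,E86,2
DA,2011,I48,1
DA,2011,S72.0,5
DA,2011,O80,1
DB,2010,I10,3
DB,2010,I11.9,1
DB,2010,I11.0,2
DB,2010,I50.1,2
DB,2010,G40.3,1
DB,2010,R56.8,1
DB,2010,J18.1,2
DB,2010,J18.0,4
DB,2010,N70.1,1
DB,2010,M16.1,6
DB,2011,C50,5
DB,2011,D50.1,1
DB,2011,D50.0,2
DB,2011,E16.2,1
DB,2011,J02,2
DB,2011,L03,1
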